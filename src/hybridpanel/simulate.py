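"""Synthetic diallel hybrid-panel generator.

Builds complete panels — strain metadata, parental genotype matrix, ploidy
bookkeeping, and long-format OD600 time series — with the statistical
structure the downstream analyses assume: Gompertz-shaped growth with a
mid-parent baseline for hybrids, heterozygosity-linked heterosis in
designated media, a per-ploidy growth penalty, and attenuation of measured
ploidy at high predicted ploidy. A ground-truth ledger of the generating
parameters is kept alongside for recovery tests but is never an analysis
input.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, predict_heterozygosity
from . import design

__all__ = [
    "MediumEffects",
    "PanelConfig",
    "SyntheticPanel",
    "default_config",
    "small_config",
    "generate_genotypes",
    "generate_panel",
    "write_panel",
    "read_panel",
]


def rng_for(seed: int, stream: str) -> np.random.Generator:
    """Named, independent random substream derived from the run seed."""
    key = zlib.crc32(stream.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class MediumEffects:
    """Per-medium generating effects for the growth model.

    ``heterozygosity_coefficient`` is the additive bump to the log-scale
    amplitude A per unit of predicted heterozygous fraction (hybrids only);
    ``ploidy_penalty`` the additive change in A per ploidy unit above 2N.
    """

    name: str
    base_A: float = 2.0
    base_mu: float = 0.25
    base_lambda: float = 10.0
    heterozygosity_coefficient: float = 0.0
    ploidy_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.base_A <= 0 or self.base_mu <= 0 or self.base_lambda < 0:
            raise ValueError(f"medium {self.name!r}: non-positive baselines")


@dataclass
class PanelConfig:
    """Configuration of one synthetic panel."""

    n_parents: int = 18
    n_sites: int = 2000
    n_clades: int = 6
    frac_domesticated: float = 12 / 18
    frac_tetraploid: float = 4 / 18
    n_sterile_parents: int = 3  # no spore-route variants
    n_spore_mata_dropped: int = 2  # lost spore-route MATa clones
    media: list[MediumEffects] = field(default_factory=list)
    n_replicates: int = 3
    time_start: float = 0.0
    time_end: float = 96.0
    time_step: float = 3.0
    base_od0: float = 0.1
    noise_sd: float = 0.01  # OD600 units, i.i.d. per reading
    param_noise_sd: float = 0.0  # extra strain-level sd on A (log-OD units)
    parent_effect_sd: float = 0.15  # per parent x medium effect sd on A
    het_site_fraction: float = 0.10  # heterozygous sites within parents
    clade_divergence: float = 0.35
    within_clade_diversity: float = 0.05
    ploidy_jitter_sd: float = 0.35
    ploidy_instability_threshold: float = 6.0
    ploidy_attenuation_width: float = 1.0  # 0 disables attenuation
    mu_effect_scale: float = 0.4  # relative strength of effects on mu vs A
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.media:
            self.media = _default_media()
        if self.n_parents < 2:
            raise ValueError("n_parents must be >= 2")
        for frac in (self.frac_domesticated, self.frac_tetraploid):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"proportion {frac} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.time_step <= 0 or self.time_end <= self.time_start:
            raise ValueError("time grid must be strictly increasing")

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.time_start, self.time_end + self.time_step / 2, self.time_step)

    def medium_names(self) -> list[str]:
        return [m.name for m in self.media]


def _default_media() -> list[MediumEffects]:
    """Six media mirroring the assayed design: control plus five stresses.

    Two stress media carry a positive heterozygosity effect; every medium
    carries a negative ploidy penalty on growth.
    """
    base = dict(base_A=2.2, base_mu=0.28, base_lambda=8.0, ploidy_penalty=-0.08)
    stress = dict(base_A=1.4, base_mu=0.15, base_lambda=16.0, ploidy_penalty=-0.08)
    return [
        MediumEffects("control", **base),
        MediumEffects("ethanol_14pct", **{**stress, "heterozygosity_coefficient": 3.0}),
        MediumEffects("nacl_1.5M", **{**stress, "heterozygosity_coefficient": 3.0}),
        MediumEffects("lactic_0.15M", **stress),
        MediumEffects("acetic_0.05M", **stress),
        MediumEffects("hmf_0.05M", **stress),
    ]


def default_config(seed: int = 0, **overrides) -> PanelConfig:
    """Full-size profile: 18 parents, 6 media, 3 replicates (~1023 hybrids)."""
    return PanelConfig(seed=seed, **overrides)


def small_config(seed: int = 0, **overrides) -> PanelConfig:
    """Fast test profile: 6 parents, 2 media, reduced site count."""
    media = [
        MediumEffects("control", base_A=2.2, base_mu=0.28, base_lambda=8.0,
                      ploidy_penalty=-0.08),
        MediumEffects("ethanol_14pct", base_A=1.4, base_mu=0.15, base_lambda=16.0,
                      ploidy_penalty=-0.08, heterozygosity_coefficient=3.0),
    ]
    defaults = dict(
        n_parents=6, n_sites=400, n_clades=3, frac_domesticated=0.5,
        frac_tetraploid=1 / 3, n_sterile_parents=1, n_spore_mata_dropped=1,
        media=media,
    )
    defaults.update(overrides)
    return PanelConfig(seed=seed, **defaults)


@dataclass
class SyntheticPanel:
    """A generated panel: metadata, genotypes, growth data and truth ledger."""

    config: PanelConfig
    strain_metadata: pd.DataFrame
    genotypes: GenotypeMatrix
    growth_data: pd.DataFrame
    truth: pd.DataFrame


def generate_genotypes(
    n_parents: int,
    n_sites: int,
    n_clades: int,
    seed: int,
    het_site_fraction: float = 0.1,
    clade_divergence: float = 0.35,
    within_clade_diversity: float = 0.05,
    strain_ids: list[str] | None = None,
) -> GenotypeMatrix:
    """Clade-structured parental genotype matrix with codes in {0, 0.5, 1}.

    Each clade draws its own per-site major allele; strains deviate from
    their clade consensus with probability ``within_clade_diversity`` and
    carry heterozygous (0.5) sites with probability ``het_site_fraction``.
    Between-clade divergence is controlled by ``clade_divergence``: the
    probability that two clades disagree at a site.
    """
    if n_parents <= 0 or n_sites <= 0 or n_clades <= 0:
        raise ValueError("counts must be positive")
    if n_clades > n_parents:
        raise ValueError(f"n_clades {n_clades} > n_parents {n_parents}")
    rng = rng_for(seed, "genotypes")
    if strain_ids is None:
        strain_ids = [f"P{i + 1:02d}" for i in range(n_parents)]
    clade_of = np.arange(n_parents) % n_clades

    # ancestral allele per site, then clade-level flips
    ancestral = rng.integers(0, 2, size=n_sites).astype(float)
    clade_geno = np.tile(ancestral[:, None], (1, n_clades))
    flips = rng.random((n_sites, n_clades)) < clade_divergence
    clade_geno[flips] = 1.0 - clade_geno[flips]

    values = clade_geno[:, clade_of].copy()
    dev = rng.random((n_sites, n_parents)) < within_clade_diversity
    values[dev] = 1.0 - values[dev]
    # heterozygous sites are clade-level (overriding strain deviations), so a
    # clade with zero within-clade diversity has exactly identical columns
    het = (rng.random((n_sites, n_clades)) < het_site_fraction)[:, clade_of]
    values[het] = 0.5

    site_ids = [f"chr1:{1000 + 10 * i}:A:G" for i in range(n_sites)]
    return GenotypeMatrix(site_ids, strain_ids, values)


def _resolve_spore_genotype(col: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Loss of heterozygosity on sporulation: each 0.5 site goes to 0 or 1."""
    out = col.copy()
    het = out == 0.5
    out[het] = rng.integers(0, 2, size=int(het.sum())).astype(float)
    return out


def _attenuate_ploidy(predicted: float, threshold: float, width: float) -> float:
    """Soft clamp of predicted ploidy toward the instability threshold."""
    if width <= 0 or predicted <= threshold:
        return predicted
    return threshold + width * np.tanh((predicted - threshold) / width)


def generate_panel(config: PanelConfig) -> SyntheticPanel:
    """Generate a complete synthetic panel (deterministic under the seed).

    Parents get ploidy in {2, 4} and domestication labels; each parent
    yields mating-competent variants by a ploidy-retaining "switch" route
    and (if fertile) a ploidy-halving "spore" route with loss of
    heterozygosity. All MATa x MATalpha pairs are crossed. Per strain and
    medium, the generating Gompertz amplitude is

        A = base_A + parent effect (mid-parent for hybrids)
            + heterozygosity_coefficient * predicted het fraction (hybrids)
            + ploidy_penalty * (measured ploidy - 2) + strain-level noise,

    with proportional (scaled) effects on mu; OD600 readings add i.i.d.
    Gaussian noise on the Gompertz curve values.
    """
    cfg = config
    n = cfg.n_parents
    parent_ids = [f"P{i + 1:02d}" for i in range(n)]

    rng_lab = rng_for(cfg.seed, "labels")
    n_dom = int(round(cfg.frac_domesticated * n))
    n_tet = int(round(cfg.frac_tetraploid * n))
    dom = np.zeros(n, dtype=bool)
    dom[rng_lab.choice(n, size=n_dom, replace=False)] = True
    tet = np.zeros(n, dtype=bool)
    tet[rng_lab.choice(n, size=n_tet, replace=False)] = True
    ploidy = np.where(tet, 4.0, 2.0)
    clade_of = np.arange(n) % cfg.n_clades

    genotypes = generate_genotypes(
        n, cfg.n_sites, cfg.n_clades, cfg.seed,
        het_site_fraction=cfg.het_site_fraction,
        clade_divergence=cfg.clade_divergence,
        within_clade_diversity=cfg.within_clade_diversity,
        strain_ids=parent_ids,
    )

    # --- mating-competent roster -------------------------------------------
    rng_routes = rng_for(cfg.seed, "routes")
    sterile = np.zeros(n, dtype=bool)
    if cfg.n_sterile_parents > 0:
        sterile[rng_routes.choice(n, size=min(cfg.n_sterile_parents, n), replace=False)] = True

    meta_rows: list[dict] = []
    geno_cols: dict[str, np.ndarray] = {}
    for i, pid in enumerate(parent_ids):
        meta_rows.append(
            dict(strain_id=pid, role="wildtype", mating_type="MATa/MATalpha",
                 parent_a="", parent_b="", ploidy_predicted=ploidy[i],
                 ploidy_measured=ploidy[i],
                 domestication="domesticated" if dom[i] else "wild",
                 clade=f"clade{clade_of[i] + 1}")
        )
        geno_cols[pid] = genotypes.column(pid)

    mata_ids: list[str] = []
    matalpha_ids: list[str] = []
    spore_mata: list[str] = []
    for i, pid in enumerate(parent_ids):
        for mt, bucket in (("MATa", mata_ids), ("MATalpha", matalpha_ids)):
            sid = f"{pid}-sw-{mt[3:]}"
            meta_rows.append(
                dict(strain_id=sid, role="mating_competent", mating_type=mt,
                     parent_a=pid, parent_b="", ploidy_predicted=ploidy[i],
                     ploidy_measured=ploidy[i],
                     domestication="domesticated" if dom[i] else "wild",
                     clade=f"clade{clade_of[i] + 1}")
            )
            geno_cols[sid] = geno_cols[pid]
            bucket.append(sid)
        if sterile[i]:
            continue
        for mt, bucket in (("MATa", mata_ids), ("MATalpha", matalpha_ids)):
            sid = f"{pid}-sp-{mt[3:]}"
            meta_rows.append(
                dict(strain_id=sid, role="mating_competent", mating_type=mt,
                     parent_a=pid, parent_b="", ploidy_predicted=ploidy[i] / 2,
                     ploidy_measured=ploidy[i] / 2,
                     domestication="domesticated" if dom[i] else "wild",
                     clade=f"clade{clade_of[i] + 1}")
            )
            geno_cols[sid] = _resolve_spore_genotype(geno_cols[pid], rng_routes)
            if mt == "MATa":
                spore_mata.append(sid)
            bucket.append(sid)

    if cfg.n_spore_mata_dropped > 0 and spore_mata:
        drop = list(
            rng_routes.choice(
                spore_mata, size=min(cfg.n_spore_mata_dropped, len(spore_mata)),
                replace=False,
            )
        )
        mata_ids = [s for s in mata_ids if s not in drop]
        meta_rows = [r for r in meta_rows if r["strain_id"] not in drop]
        for sid in drop:
            geno_cols.pop(sid)

    meta = pd.DataFrame(meta_rows)
    mc_ploidy = meta.set_index("strain_id")["ploidy_measured"]

    # --- hybrids ------------------------------------------------------------
    rng_ploidy = rng_for(cfg.seed, "ploidy")
    hyb_rows: list[dict] = []
    dom_of = meta.set_index("strain_id")["domestication"]
    for a in mata_ids:
        for b in matalpha_ids:
            hid = f"H-{a}x{b}"
            pred = float(mc_ploidy[a] + mc_ploidy[b])
            att = _attenuate_ploidy(
                pred, cfg.ploidy_instability_threshold, cfg.ploidy_attenuation_width
            )
            measured = max(att + rng_ploidy.normal(0.0, cfg.ploidy_jitter_sd), 1.0)
            dom_pair = sorted([dom_of[a], dom_of[b]])
            hyb_rows.append(
                dict(strain_id=hid, role="hybrid", mating_type="MATa/MATalpha",
                     parent_a=a, parent_b=b, ploidy_predicted=pred,
                     ploidy_measured=measured,
                     domestication="NA",
                     clade="NA")
            )
    meta = pd.concat([meta, pd.DataFrame(hyb_rows)], ignore_index=True)

    # --- generating growth parameters ---------------------------------------
    rng_eff = rng_for(cfg.seed, "effects")
    # per parent x medium additive effect on A (shared by derived strains)
    parent_effect = {
        (pid, m.name): rng_eff.normal(0.0, cfg.parent_effect_sd)
        for pid in parent_ids for m in cfg.media
    }
    het_frac: dict[str, float] = {}
    for row in meta.itertuples():
        if row.role == "hybrid":
            het = predict_heterozygosity(geno_cols[row.parent_a], geno_cols[row.parent_b])
            het_frac[row.strain_id] = het / cfg.n_sites

    wt_of: dict[str, str] = {}
    for row in meta.itertuples():
        if row.role == "wildtype":
            wt_of[row.strain_id] = row.strain_id
        elif row.role == "mating_competent":
            wt_of[row.strain_id] = row.parent_a

    rng_param = rng_for(cfg.seed, "param_noise")
    truth_rows: list[dict] = []
    for row in meta.itertuples():
        for m in cfg.media:
            if row.role == "hybrid":
                ea = parent_effect[(wt_of[row.parent_a], m.name)]
                eb = parent_effect[(wt_of[row.parent_b], m.name)]
                eff = 0.5 * (ea + eb)
                het_term = m.heterozygosity_coefficient * het_frac[row.strain_id]
            else:
                eff = parent_effect[(wt_of[row.strain_id], m.name)]
                het_term = 0.0
            ploidy_term = m.ploidy_penalty * (row.ploidy_measured - 2.0)
            noise = rng_param.normal(0.0, cfg.param_noise_sd) if cfg.param_noise_sd > 0 else 0.0
            g = eff + het_term + ploidy_term + noise
            A = max(m.base_A + g, 0.05)
            mu = max(m.base_mu * (1.0 + cfg.mu_effect_scale * g / m.base_A), 0.01)
            lam = m.base_lambda
            truth_rows.append(
                dict(strain_id=row.strain_id, medium=m.name, A=A, mu=mu, lam=lam,
                     od0=cfg.base_od0, het_fraction=het_frac.get(row.strain_id, 0.0),
                     het_term=het_term, ploidy_term=ploidy_term,
                     parent_effect=eff, param_noise=noise,
                     ploidy_predicted=row.ploidy_predicted,
                     ploidy_measured=row.ploidy_measured)
            )
    truth = pd.DataFrame(truth_rows)

    # --- OD600 time series ----------------------------------------------------
    from .growth import gompertz_log  # local import to avoid cycle at module load

    rng_noise = rng_for(cfg.seed, "od_noise")
    t = cfg.time_grid
    n_t = t.size
    frames: list[pd.DataFrame] = []
    for tr in truth.itertuples():
        clean = cfg.base_od0 * np.exp(gompertz_log(t, tr.A, tr.mu, tr.lam))
        for rep in range(1, cfg.n_replicates + 1):
            od = clean + rng_noise.normal(0.0, cfg.noise_sd, n_t) if cfg.noise_sd > 0 else clean.copy()
            np.maximum(od, 1e-4, out=od)
            frames.append(
                pd.DataFrame(
                    {
                        "strain_id": tr.strain_id,
                        "medium": tr.medium,
                        "replicate": rep,
                        "time_h": t,
                        "od600": od,
                    }
                )
            )
    growth_data = pd.concat(frames, ignore_index=True)

    all_geno = GenotypeMatrix(
        genotypes.site_ids,
        list(geno_cols.keys()),
        np.column_stack([geno_cols[s] for s in geno_cols]),
    )
    return SyntheticPanel(cfg, meta, all_geno, growth_data, truth)


_GROWTH_COLS = ["strain_id", "medium", "replicate", "time_h", "od600"]
_META_COLS = [
    "strain_id", "role", "mating_type", "parent_a", "parent_b",
    "ploidy_predicted", "ploidy_measured", "domestication", "clade",
]


def write_panel(panel: SyntheticPanel, directory) -> dict[str, Path]:
    """Write a panel to delimited text files; returns the path map.

    The truth ledger goes to ``truth.tsv`` for recovery tests only — the
    analysis stages must never read it.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "growth": directory / "growth.tsv",
        "metadata": directory / "metadata.tsv",
        "genotypes": directory / "genotypes.tsv",
        "truth": directory / "truth.tsv",
    }
    panel.growth_data[_GROWTH_COLS].to_csv(
        paths["growth"], sep="\t", index=False, float_format="%.10g"
    )
    panel.strain_metadata[_META_COLS].to_csv(
        paths["metadata"], sep="\t", index=False, float_format="%.10g"
    )
    panel.genotypes.write_tsv(paths["genotypes"])
    panel.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    return paths


def read_panel(directory) -> tuple[pd.DataFrame, pd.DataFrame, GenotypeMatrix]:
    """Read back the analysis inputs (growth, metadata, genotypes) — not truth."""
    directory = Path(directory)
    growth = pd.read_csv(directory / "growth.tsv", sep="\t")
    growth = growth.astype({"time_h": float, "od600": float, "replicate": int})
    meta = pd.read_csv(
        directory / "metadata.tsv", sep="\t",
        keep_default_na=False,
        dtype={"parent_a": str, "parent_b": str},
    )
    geno = GenotypeMatrix.read_tsv(directory / "genotypes.tsv")
    return growth, meta, geno
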