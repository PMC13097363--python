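"""End-to-end pipeline: simulate/load -> validate -> fit -> heterosis ->
genotype predictions -> associations, with a reproducibility manifest.

All stage outputs are delimited text written with a fixed float format so
identical config + seed yields byte-identical files. Stage results are
cached by content hash: a rerun into the same output directory reuses a
stage's table when its inputs (and options) are unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations as assoc
from . import genotypes as gt
from . import growth
from . import heterosis as het
from . import simulate

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "write_table", "read_growth_table"]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path: Path) -> None:
    """Deterministic TSV writer (fixed float format, LF line endings)."""
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _hash_bytes(*parts: bytes) -> str:
    h = hashlib.sha256()
    for p in parts:
        h.update(p)
    return h.hexdigest()


def _hash_file(path: Path) -> str:
    return _hash_bytes(Path(path).read_bytes())


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    In simulate mode a synthetic panel is generated from ``panel``;
    otherwise ``growth_path``/``metadata_path``/``genotypes_path`` must
    point to existing input tables.
    """

    outdir: Path
    seed: int = 0
    simulate: bool = True
    panel: simulate.PanelConfig | None = None
    growth_path: Path | None = None
    metadata_path: Path | None = None
    genotypes_path: Path | None = None
    fit_options: growth.FitOptions = field(default_factory=growth.FitOptions)
    horizon: float = 96.0
    grid_step: float = 3.0
    parent_reference: str = "mating_competent"
    bin_edges: tuple[float, ...] = (2.5, 3.5, 4.5)
    bph_floor: float = 1e-9

    def config_hash(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (Path, np.floating, np.integer)):
                return str(obj)
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj
        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return _hash_bytes(payload.encode())


def read_growth_table(path) -> pd.DataFrame:
    """Read a growth TSV, pinpointing corrupt rows by file, line and field."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = ["strain_id", "medium", "replicate", "time_h", "od600"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("time_h", "od600"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            i = int(bad.idxmax())
            # +2: one for the header line, one for 1-based numbering
            raise ValueError(
                f"{path}: line {i + 2}: field {col!r}: "
                f"not numeric: {df[col].iloc[i]!r}"
            )
        df[col] = coerced.astype(float)
    return df


def validate_inputs(
    growth_df: pd.DataFrame,
    metadata: pd.DataFrame,
    genotypes: gt.GenotypeMatrix | pd.DataFrame | None,
) -> list[dict]:
    """Schema and referential checks; returns a list of issue records."""
    issues: list[dict] = []

    required = ["strain_id", "medium", "replicate", "time_h", "od600"]
    missing = [c for c in required if c not in growth_df.columns]
    if missing:
        issues.append({"table": "growth", "issue": f"missing columns {missing}"})
        return issues
    if (growth_df["od600"] < 0).any():
        n = int((growth_df["od600"] < 0).sum())
        issues.append({"table": "growth", "issue": f"{n} negative od600 readings"})
    for well, grp in growth_df.groupby(["strain_id", "medium", "replicate"]):
        if not grp["time_h"].is_monotonic_increasing:
            issues.append({"table": "growth", "issue": f"times not sorted in well {well}"})
            break

    known = set(metadata["strain_id"])
    hybrids = metadata[metadata["role"] == "hybrid"]
    for row in hybrids.itertuples():
        for parent in (row.parent_a, row.parent_b):
            if parent not in known:
                issues.append(
                    {"table": "metadata",
                     "issue": f"hybrid {row.strain_id} references unknown parent {parent}"}
                )
    growth_strains = set(growth_df["strain_id"])
    orphans = growth_strains - known
    if orphans:
        issues.append(
            {"table": "growth",
             "issue": f"{len(orphans)} strains lack metadata (e.g. {sorted(orphans)[:3]})"}
        )
    if genotypes is not None:
        if isinstance(genotypes, gt.GenotypeMatrix):
            codes = genotypes.values
        else:
            codes = genotypes.drop(columns=["site_id"], errors="ignore").to_numpy(dtype=float)
        bad = ~np.isin(codes, (0.0, 0.5, 1.0))
        if bad.any():
            issues.append(
                {"table": "genotypes", "issue": f"{int(bad.sum())} codes outside {{0,0.5,1}}"}
            )
    return issues


def _hybrid_records(
    summaries: pd.DataFrame,
    metadata: pd.DataFrame,
    het_auc: pd.DataFrame,
    het_mu: pd.DataFrame,
    crosses: pd.DataFrame,
) -> pd.DataFrame:
    """Per hybrid x medium analysis table joining traits, heterosis,
    genetic predictions, ploidy and cross-type labels."""
    hybrids = metadata[metadata["role"] == "hybrid"].set_index("strain_id")
    wt_of = metadata.set_index("strain_id")["parent_a"].to_dict()
    cross_type = assoc.label_cross_type(metadata)

    sums = summaries.set_index(["strain_id", "medium"])
    ckey = {}
    for row in crosses.itertuples():
        ckey[(row.parent_a, row.parent_b)] = row
        ckey[(row.parent_b, row.parent_a)] = row

    base = het_auc.rename(columns={"mph": "mph_auc", "bph": "bph_auc"})
    mu_map = het_mu.set_index(["hybrid_id", "medium"])
    rows = []
    for r in base.itertuples():
        hyb = hybrids.loc[r.hybrid_id]
        cross = ckey.get((r.parent_a, r.parent_b))
        try:
            mu_rec = mu_map.loc[(r.hybrid_id, r.medium)]
            mph_mu, bph_mu = float(mu_rec["mph"]), float(mu_rec["bph"])
        except KeyError:
            mph_mu = bph_mu = np.nan
        rows.append(
            {
                "hybrid_id": r.hybrid_id,
                "medium": r.medium,
                "parent_a": r.parent_a,
                "parent_b": r.parent_b,
                "wt_parent_a": wt_of.get(r.parent_a, r.parent_a),
                "wt_parent_b": wt_of.get(r.parent_b, r.parent_b),
                "auc": float(sums.loc[(r.hybrid_id, r.medium), "mean_auc"]),
                "mu": float(sums.loc[(r.hybrid_id, r.medium), "mean_mu"]),
                "mph_auc": r.mph_auc,
                "bph_auc": r.bph_auc,
                "mph_mu": mph_mu,
                "bph_mu": bph_mu,
                "excluded": r.excluded,
                "ploidy_predicted": float(hyb["ploidy_predicted"]),
                "ploidy_measured": float(hyb["ploidy_measured"]),
                "het_sites": int(cross.het_sites) if cross else np.nan,
                "het_fraction": float(cross.het_fraction) if cross else np.nan,
                "ibs_distance": int(cross.ibs_distance) if cross else np.nan,
                "cross_type": cross_type.get(r.hybrid_id, pd.NA),
            }
        )
    return pd.DataFrame(rows)


def _association_tables(records: pd.DataFrame, metadata, summaries) -> dict[str, pd.DataFrame]:
    """All association outputs from the hybrid analysis table."""
    out: dict[str, pd.DataFrame] = {}

    # parent-grouped correlation grids: every hybrid contributes to both of
    # its wild-type parents' columns
    long = pd.concat(
        [
            records.assign(parent_id=records["wt_parent_a"]),
            records.assign(parent_id=records["wt_parent_b"]),
        ],
        ignore_index=True,
    )
    ok = long[~long["excluded"]]
    out["corr_ploidy_auc_by_parent"] = assoc.grouped_correlation(
        long, ["parent_id", "medium"], "ploidy_measured", "auc"
    )
    out["corr_ploidy_bph_by_parent"] = assoc.grouped_correlation(
        ok, ["parent_id", "medium"], "ploidy_measured", "bph_auc"
    )
    out["corr_gdist_bph_by_parent"] = assoc.grouped_correlation(
        ok, ["parent_id", "medium"], "ibs_distance", "bph_auc"
    )

    okr = records[~records["excluded"]]
    out["corr_overall_by_medium"] = pd.concat(
        [
            assoc.grouped_correlation(records, ["medium"], "ploidy_measured", "auc"),
            assoc.grouped_correlation(okr, ["medium"], "ploidy_measured", "bph_auc"),
            assoc.grouped_correlation(okr, ["medium"], "het_sites", "bph_auc"),
            assoc.grouped_correlation(okr, ["medium"], "ibs_distance", "bph_auc"),
        ],
        ignore_index=True,
    )

    # DD/DW/WW and ploidy-bin comparisons per medium
    comp_rows = []
    labelled = records.dropna(subset=["cross_type"])
    binned = records.assign(ploidy_bin=assoc.bin_ploidy(records["ploidy_measured"]).to_numpy())
    for medium, grp in labelled.groupby("medium"):
        if grp["cross_type"].nunique() >= 2:
            try:
                c = assoc.compare_groups(grp["auc"], grp["cross_type"], "anova_tukey")
                comp_rows.append(_comparison_row(medium, "auc_by_cross_type", c))
                okg = grp[~grp["excluded"]]
                c = assoc.compare_groups(okg["bph_auc"], okg["cross_type"], "anova_tukey")
                comp_rows.append(_comparison_row(medium, "bph_by_cross_type", c))
            except ValueError as exc:
                log.warning("%s cross-type comparison skipped: %s", medium, exc)
    for medium, grp in binned.groupby("medium"):
        grp = grp[grp["ploidy_bin"].notna()]
        counts = grp["ploidy_bin"].value_counts()
        keep = counts[counts >= 2].index
        grp = grp[grp["ploidy_bin"].isin(keep)]
        if grp["ploidy_bin"].nunique() >= 2:
            c = assoc.compare_groups(
                grp["auc"], grp["ploidy_bin"].astype(str), "anova_tukey"
            )
            comp_rows.append(_comparison_row(medium, "auc_by_ploidy_bin", c))
    out["group_comparisons"] = pd.DataFrame(comp_rows)

    # hybrids vs mating-competent parents, per medium (rank-sum)
    wil_rows = []
    roles = metadata.set_index("strain_id")["role"]
    sums = summaries.copy()
    sums["role"] = sums["strain_id"].map(roles)
    for medium, grp in sums.groupby("medium"):
        hyb = grp.loc[grp["role"] == "hybrid", "mean_auc"]
        par = grp.loc[grp["role"] == "mating_competent", "mean_auc"]
        if len(hyb) and len(par):
            c = assoc.compare_groups(
                np.concatenate([hyb, par]),
                np.array(["hybrid"] * len(hyb) + ["parent"] * len(par)),
                "wilcoxon",
            )
            wil_rows.append(
                {"medium": medium, "comparison": "hybrid_vs_parent_auc",
                 "statistic": c.statistic, "p_value": c.p_value,
                 "mean_hybrid": c.group_means["hybrid"],
                 "mean_parent": c.group_means["parent"]}
            )
    out["hybrid_vs_parent"] = pd.DataFrame(wil_rows)

    # no-intercept heterosis regression per medium
    out["regression"] = assoc.fit_heterosis_model(
        okr.rename(columns={"bph_auc": "bph"}),
        g_col="ibs_distance", p_col="ploidy_measured",
    )
    return out


def _comparison_row(medium: str, name: str, c: assoc.GroupComparison) -> dict:
    return {
        "medium": medium,
        "comparison": name,
        "test": c.test,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "letters": ";".join(f"{g}={l}" for g, l in sorted((c.letters or {}).items())),
        "group_means": ";".join(f"{g}={m:.6g}" for g, m in sorted(c.group_means.items())),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write tables plus ``manifest.json``.

    Returns the manifest dict. Raises with the failing stage named.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "warnings": [],
    }
    prev = None
    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        try:
            prev = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            prev = None

    def cached(stage: str, input_hash: str, paths: list[Path]) -> bool:
        if prev is None:
            return False
        rec = prev.get("stages", {}).get(stage)
        return (
            rec is not None
            and rec.get("input_hash") == input_hash
            and all(p.exists() for p in paths)
        )

    # --- stage: inputs -------------------------------------------------------
    try:
        if config.simulate:
            panel_cfg = config.panel or simulate.default_config(seed=config.seed)
            sim_hash = _hash_bytes(
                json.dumps(dataclasses.asdict(panel_cfg), sort_keys=True, default=str).encode()
            )
            in_paths = [outdir / f"{n}.tsv" for n in ("growth", "metadata", "genotypes")]
            if cached("simulate", sim_hash, in_paths):
                growth_df, metadata, genomatrix = simulate.read_panel(outdir)
            else:
                panel = simulate.generate_panel(panel_cfg)
                simulate.write_panel(panel, outdir)
                growth_df, metadata, genomatrix = simulate.read_panel(outdir)
            manifest["stages"]["simulate"] = {
                "input_hash": sim_hash,
                "rows": {"growth": len(growth_df), "metadata": len(metadata),
                         "genotype_sites": genomatrix.n_sites},
            }
        else:
            for name in ("growth_path", "metadata_path", "genotypes_path"):
                p = getattr(config, name)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"analysis mode requires {name} ({p})")
            growth_df = read_growth_table(config.growth_path)
            metadata = pd.read_csv(
                config.metadata_path, sep="\t", keep_default_na=False,
                dtype={"parent_a": str, "parent_b": str},
            )
            genomatrix = gt.GenotypeMatrix.read_tsv(config.genotypes_path)
            manifest["stages"]["inputs"] = {
                "checksums": {
                    "growth": _hash_file(config.growth_path),
                    "metadata": _hash_file(config.metadata_path),
                    "genotypes": _hash_file(config.genotypes_path),
                }
            }
    except Exception as exc:
        raise RuntimeError(f"stage 'inputs' failed: {exc}") from exc

    # --- stage: validate -----------------------------------------------------
    issues = validate_inputs(growth_df, metadata, genomatrix)
    manifest["stages"]["validate"] = {"n_issues": len(issues), "issues": issues}
    if issues:
        manifest["warnings"].extend(str(i) for i in issues)

    # --- stage: fit ----------------------------------------------------------
    fit_path = outdir / "fits.tsv"
    summary_path = outdir / "summaries.tsv"
    fit_hash = _hash_bytes(
        json.dumps(
            {"growth_rows": len(growth_df),
             "growth_hash": _hash_bytes(
                 pd.util.hash_pandas_object(growth_df, index=False).values.tobytes()),
             "options": dataclasses.asdict(config.fit_options),
             "horizon": config.horizon, "grid_step": config.grid_step},
            sort_keys=True,
        ).encode()
    )
    try:
        if cached("fit", fit_hash, [fit_path, summary_path]):
            fits = pd.read_csv(fit_path, sep="\t")
            summaries = pd.read_csv(summary_path, sep="\t")
        else:
            fits = growth.fit_growth_table(
                growth_df, config.fit_options, config.horizon, config.grid_step
            )
            summaries = growth.summary_table(fits)
            write_table(fits, fit_path)
            write_table(summaries, summary_path)
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    manifest["stages"]["fit"] = {
        "input_hash": fit_hash,
        "rows": {"fits": len(fits), "summaries": len(summaries)},
        "n_no_growth": int(fits["no_growth"].sum()),
        "median_cv_auc": growth.dataset_median_cv(summaries, "auc"),
        "median_cv_mu": growth.dataset_median_cv(summaries, "mu"),
    }

    # --- stage: heterosis ----------------------------------------------------
    try:
        het_auc = het.heterosis_table(summaries, metadata, "auc", config.parent_reference)
        het_mu = het.heterosis_table(summaries, metadata, "mu", config.parent_reference)
        write_table(het_auc, outdir / "heterosis_auc.tsv")
        write_table(het_mu, outdir / "heterosis_mu.tsv")
        rep = het.parent_representation(het_auc, metadata)
        write_table(rep, outdir / "parent_representation.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'heterosis' failed: {exc}") from exc
    manifest["stages"]["heterosis"] = {
        "auc": het.positive_counts(het_auc),
        "mu": het.positive_counts(het_mu),
    }

    # --- stage: genotype -----------------------------------------------------
    try:
        crosses = gt.cross_predictions(genomatrix, metadata)
        write_table(crosses, outdir / "cross_predictions.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'genotype' failed: {exc}") from exc
    manifest["stages"]["genotype"] = {"rows": len(crosses)}

    # --- stage: associate ----------------------------------------------------
    try:
        records = _hybrid_records(summaries, metadata, het_auc, het_mu, crosses)
        write_table(records, outdir / "hybrid_records.tsv")
        tables = _association_tables(records, metadata, summaries)
        for name, df in tables.items():
            write_table(df, outdir / f"{name}.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'associate' failed: {exc}") from exc
    manifest["stages"]["associate"] = {
        "rows": {name: len(df) for name, df in tables.items()},
        "hybrid_records": len(records),
    }

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
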