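"""Genotype-matrix construction and cross-level genetic predictions.

Genotypes are coded on a per-site scale of ``0`` (homozygous reference),
``0.5`` (heterozygous) and ``1`` (homozygous alternate), built from diploid
GT calls in a VCF. From a pair of parental genotype columns the module
predicts the heterozygous-site count of their hybrid (sites whose mean code
is neither 0 nor 1), the identity-by-state (IBS) distance (count of IBS0 +
IBS1 sites), and the hybrid's predicted ploidy (sum of parental ploidies).
A linear fluorescence standard curve converts flow-cytometry intensities to
measured ploidy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PloidyStandardCurve",
    "load_genotype_matrix",
    "predict_heterozygosity",
    "ibs_counts",
    "ibs_distance",
    "cross_predictions",
    "fit_standard_curve",
    "ploidy_from_intensity",
]

_VALID_CODES = (0.0, 0.5, 1.0)


@dataclass
class GenotypeMatrix:
    """Sites x strains matrix of genotype codes in {0, 0.5, 1}.

    Attributes
    ----------
    site_ids : list of str
        Unique site identifiers (``chrom:pos:ref:alt``), in file order.
    strain_ids : list of str
        Unique strain identifiers, column order.
    values : ndarray of shape (n_sites, n_strains)
        Genotype codes; every entry must be 0, 0.5 or 1 (no missing data).
    """

    site_ids: list[str]
    strain_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.strain_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.strain_ids)} strains"
            )
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site ids are not unique")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("strain ids are not unique")
        if not np.isin(self.values, _VALID_CODES).all():
            bad = self.values[~np.isin(self.values, _VALID_CODES)]
            raise ValueError(f"genotype codes outside {{0, 0.5, 1}}: {bad[:5]}")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    def column(self, strain_id: str) -> np.ndarray:
        """Genotype column for one strain."""
        try:
            j = self.strain_ids.index(strain_id)
        except ValueError:
            raise KeyError(f"strain {strain_id!r} not in matrix") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.strain_ids)
        df.insert(0, "site_id", self.site_ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        if "site_id" not in df.columns:
            raise ValueError("genotype table must have a 'site_id' column")
        strains = [c for c in df.columns if c != "site_id"]
        return cls(
            site_ids=[str(s) for s in df["site_id"]],
            strain_ids=strains,
            values=df[strains].to_numpy(dtype=float),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.1f")

    @classmethod
    def read_tsv(cls, path) -> "GenotypeMatrix":
        return cls.from_frame(pd.read_csv(path, sep="\t"))


def load_genotype_matrix(
    vcf_path, quality_min: float = 30.0, snps_only: bool = False
) -> GenotypeMatrix:
    """Build a genotype matrix from a VCF of jointly called diploid genotypes.

    Sites are retained only if the record QUAL is at least ``quality_min``
    (default 30), the site is biallelic, and every sample carries a complete
    diploid GT. Codes: 0/0 -> 0, 0/1 or 1/0 -> 0.5, 1/1 -> 1. Site order
    follows file order. With ``snps_only`` indel records are dropped too.

    Raises
    ------
    ValueError
        If a retained record carries a non-diploid GT, or if no site
        survives filtering.
    """
    from cyvcf2 import VCF  # deferred: only needed for VCF input

    vcf = VCF(str(vcf_path))
    strain_ids = list(vcf.samples)
    site_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if var.QUAL is None or var.QUAL < quality_min:
            continue
        if len(var.ALT) != 1:
            continue
        if snps_only and not var.is_snp:
            continue
        codes = np.empty(len(strain_ids))
        ok = True
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid GT at {var.CHROM}:{var.POS} sample "
                    f"{strain_ids[i]}: ploidy {len(alleles)}"
                )
            a, b = alleles
            if a < 0 or b < 0:  # missing genotype
                ok = False
                break
            if a > 1 or b > 1:
                ok = False  # allele index beyond biallelic coding
                break
            codes[i] = (a + b) / 2.0
        if not ok:
            continue
        site_ids.append(f"{var.CHROM}:{var.POS}:{var.REF}:{var.ALT[0]}")
        rows.append(codes)
    vcf.close()
    if not rows:
        raise ValueError(
            f"no sites in {vcf_path} survive filtering "
            f"(quality >= {quality_min}, biallelic, complete genotypes)"
        )
    return GenotypeMatrix(site_ids, strain_ids, np.vstack(rows))


def _check_columns(col_a: np.ndarray, col_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"column length mismatch: {a.shape} vs {b.shape}")
    return a, b


def predict_heterozygosity(col_a: np.ndarray, col_b: np.ndarray) -> int:
    """Predicted heterozygous-site count of the hybrid of two parents.

    Per site the mean of the two parental codes is taken; the site is
    predicted heterozygous when that mean is neither 0 nor 1.
    """
    a, b = _check_columns(col_a, col_b)
    mean = (a + b) / 2.0
    return int(np.sum((mean != 0.0) & (mean != 1.0)))


def ibs_counts(col_a: np.ndarray, col_b: np.ndarray) -> tuple[int, int, int]:
    """Counts of IBS0, IBS1 and IBS2 sites between two genotype columns.

    Under biallelic diploid coding, sites with identical codes share both
    alleles (IBS2), codes differing by 0.5 share one (IBS1), and codes 0 vs
    1 share none (IBS0).
    """
    a, b = _check_columns(col_a, col_b)
    diff = np.abs(a - b)
    ibs0 = int(np.sum(diff == 1.0))
    ibs1 = int(np.sum(diff == 0.5))
    ibs2 = int(np.sum(diff == 0.0))
    return ibs0, ibs1, ibs2


def ibs_distance(col_a: np.ndarray, col_b: np.ndarray) -> int:
    """Genetic distance between two strains: the IBS0 + IBS1 site count."""
    ibs0, ibs1, _ = ibs_counts(col_a, col_b)
    return ibs0 + ibs1


def cross_predictions(
    matrix: GenotypeMatrix,
    metadata: pd.DataFrame,
    ploidy_col: str = "ploidy_measured",
) -> pd.DataFrame:
    """Per-parent-pair genetic predictions for every cross in ``metadata``.

    ``metadata`` must contain hybrid rows (``role == "hybrid"``) whose
    ``parent_a``/``parent_b`` reference strains present both in ``matrix``
    and in ``metadata`` with a ploidy in ``ploidy_col``. One row per
    unordered parent pair is returned with the predicted heterozygous-site
    count, IBS class counts, IBS distance (raw and normalized) and
    predicted hybrid ploidy (sum of parental ploidies).
    """
    hybrids = metadata[metadata["role"] == "hybrid"]
    ploidy = metadata.set_index("strain_id")[ploidy_col]
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for pa, pb in zip(hybrids["parent_a"], hybrids["parent_b"]):
        key = (pa, pb) if pa <= pb else (pb, pa)
        if key not in seen:
            seen.add(key)
            pairs.append(key)
    rows = []
    n = matrix.n_sites
    for pa, pb in pairs:
        try:
            col_a, col_b = matrix.column(pa), matrix.column(pb)
        except KeyError as exc:
            raise KeyError(f"cross {pa} x {pb}: {exc}") from None
        het = predict_heterozygosity(col_a, col_b)
        ibs0, ibs1, ibs2 = ibs_counts(col_a, col_b)
        rows.append(
            {
                "parent_a": pa,
                "parent_b": pb,
                "het_sites": het,
                "het_fraction": het / n,
                "ibs0": ibs0,
                "ibs1": ibs1,
                "ibs2": ibs2,
                "ibs_distance": ibs0 + ibs1,
                "ibs_distance_norm": (ibs0 + ibs1) / n,
                "ploidy_predicted": float(ploidy[pa] + ploidy[pb]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PloidyStandardCurve:
    """Linear fluorescence-vs-ploidy standard curve from control strains."""

    control_intensities: np.ndarray
    control_ploidies: np.ndarray
    slope: float
    intercept: float
    r_squared: float


def fit_standard_curve(
    control_intensities, control_ploidies
) -> PloidyStandardCurve:
    """Least-squares line intensity = slope * ploidy + intercept.

    Requires at least two distinct control ploidies and a positive slope
    (fluorescence must increase with DNA content).
    """
    inten = np.asarray(control_intensities, dtype=float)
    plo = np.asarray(control_ploidies, dtype=float)
    if inten.shape != plo.shape:
        raise ValueError("control arrays differ in length")
    if len(np.unique(plo)) < 2:
        raise ValueError("standard curve needs >= 2 distinct control ploidies")
    slope, intercept = np.polyfit(plo, inten, 1)
    if slope <= 0:
        raise ValueError(f"degenerate standard curve: slope {slope:.4g} <= 0")
    pred = slope * plo + intercept
    ss_res = float(np.sum((inten - pred) ** 2))
    ss_tot = float(np.sum((inten - inten.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return PloidyStandardCurve(inten, plo, float(slope), float(intercept), r2)


def ploidy_from_intensity(intensity: float, curve: PloidyStandardCurve) -> float:
    """Invert the standard curve: ploidy = (intensity - intercept) / slope."""
    ploidy = (float(intensity) - curve.intercept) / curve.slope
    if ploidy < 0:
        raise ValueError(
            f"intensity {intensity} maps to negative ploidy {ploidy:.3g}"
        )
    return ploidy
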