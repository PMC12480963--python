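"""RT-qPCR relative quantification: standard curves, geNorm, fold changes.

Quantification cycle (Ct) values are converted to relative quantities
against a per-gene standard curve fitted to a serial-dilution series:
``Ct = slope·log10(q) + intercept`` with amplification efficiency
``E = 10^(−1/slope) − 1`` (slope −3.3219 ⇔ 100%). Reference-gene stability
is ranked with the geNorm measure M — for gene j, the mean over the other
candidate genes k of the standard deviation across samples of
``log2(q_j/q_k)`` — and normalization factors are geometric means of the
chosen reference genes' quantities. Fold changes are ratios of group
geometric means of normalized quantities.

Plates are long-format DataFrames with columns ``gene``, ``sample``,
``group``, ``replicate``, ``ct``, ``is_dilution_standard``,
``dilution_factor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PLATE_COLUMNS",
    "StandardCurve",
    "GeNormResult",
    "validate_plate",
    "fit_standard_curve",
    "relative_quantity",
    "quantity_table",
    "genorm_m",
    "genorm_ranking",
    "pairwise_variation",
    "normalization_and_fold_change",
]

PLATE_COLUMNS = [
    "gene",
    "sample",
    "group",
    "replicate",
    "ct",
    "is_dilution_standard",
    "dilution_factor",
]


def validate_plate(plate: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PLATE_COLUMNS if c not in plate.columns]
    if missing:
        raise ValueError(f"plate is missing columns {missing}")
    if not np.isfinite(plate["ct"]).all():
        raise ValueError("plate contains non-finite Ct values")
    return plate


@dataclass
class StandardCurve:
    """Dilution-series calibration for one gene.

    ``efficiency`` is the per-cycle amplification gain in (0, 1]; values
    outside the (0.8, 1.1) band are flagged but still usable. A positive
    slope cannot come from a real dilution series and marks the curve
    invalid.
    """

    gene: str
    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0

    @property
    def valid(self) -> bool:
        return self.slope < 0

    @property
    def efficiency_warning(self) -> bool:
        return not (0.8 < self.efficiency < 1.1)


def fit_standard_curve(plate: pd.DataFrame, gene: str) -> StandardCurve:
    """Least-squares fit of mean Ct against log10 relative input.

    Dilution standards for the gene are grouped by dilution factor (the
    relative input quantity); at least three distinct factors are required.
    """
    validate_plate(plate)
    std = plate[(plate["gene"] == gene) & plate["is_dilution_standard"]]
    if std["dilution_factor"].nunique() < 3:
        raise ValueError(
            f"standard curve for {gene!r} needs >= 3 distinct dilution points, "
            f"got {std['dilution_factor'].nunique()}"
        )
    mean_ct = std.groupby("dilution_factor")["ct"].mean()
    x = np.log10(mean_ct.index.to_numpy(dtype=float))
    y = mean_ct.to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return StandardCurve(
        gene=gene,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
    )


def relative_quantity(ct: float | np.ndarray, curve: StandardCurve):
    """Relative input quantity for a Ct value: ``10^((ct − intercept)/slope)``."""
    if not curve.valid:
        raise ValueError(f"invalid standard curve for {curve.gene!r} (slope >= 0)")
    return 10.0 ** ((np.asarray(ct, dtype=float) - curve.intercept) / curve.slope)


def quantity_table(
    plate: pd.DataFrame, curves: dict[str, StandardCurve] | None = None
) -> pd.DataFrame:
    """Per-(gene, sample) relative quantities, replicates aggregated.

    Technical replicates are combined by geometric mean on the quantity
    scale (Ct is log-scale, so this is the arithmetic mean Ct); the per-
    sample quantity CV across replicates is reported alongside. Curves are
    fitted from the plate's own dilution series when not supplied.
    """
    validate_plate(plate)
    samples = plate[~plate["is_dilution_standard"]]
    genes = samples["gene"].unique()
    if curves is None:
        curves = {g: fit_standard_curve(plate, g) for g in genes}
    rows = []
    for (gene, sample), grp in samples.groupby(["gene", "sample"], sort=True):
        q = relative_quantity(grp["ct"].to_numpy(), curves[gene])
        geo = float(np.exp(np.mean(np.log(q))))
        cv = float(np.std(q, ddof=1) / np.mean(q)) if len(q) > 1 else np.nan
        rows.append(
            {
                "gene": gene,
                "sample": sample,
                "group": grp["group"].iloc[0],
                "quantity": geo,
                "replicate_cv": cv,
                "n_replicates": len(q),
            }
        )
    return pd.DataFrame(rows)


def _wide_quantities(qtable: pd.DataFrame) -> pd.DataFrame:
    wide = qtable.pivot(index="sample", columns="gene", values="quantity")
    if wide.isna().any().any():
        raise ValueError("quantity table has missing (gene, sample) cells")
    if (wide <= 0).any().any():
        raise ValueError("quantities must be positive")
    return wide


def genorm_m(qtable: pd.DataFrame, genes: list[str] | None = None) -> pd.Series:
    """geNorm stability measure M per candidate reference gene.

    M_j = mean over the other genes k of the standard deviation (across
    samples, n−1 denominator) of log2(q_j / q_k). Lower M = more stable.
    Invariant to global rescaling of any gene and to sample relabelling.
    """
    wide = _wide_quantities(qtable)
    if genes is not None:
        wide = wide[list(genes)]
    if wide.shape[1] < 2 or wide.shape[0] < 2:
        raise ValueError("geNorm needs >= 2 genes and >= 2 samples")
    logq = np.log2(wide.to_numpy())
    n_genes = logq.shape[1]
    m = np.empty(n_genes)
    for j in range(n_genes):
        sds = [
            np.std(logq[:, j] - logq[:, k], ddof=1)
            for k in range(n_genes)
            if k != j
        ]
        m[j] = float(np.mean(sds))
    return pd.Series(m, index=wide.columns, name="M")


def genorm_ranking(qtable: pd.DataFrame) -> list[str]:
    """Stability ranking by iterative exclusion of the least stable gene.

    Returns genes from least to most stable; the final two (which cannot be
    ranked against each other) come last, most stable at the end.
    """
    wide = _wide_quantities(qtable)
    remaining = list(wide.columns)
    excluded: list[str] = []
    while len(remaining) > 2:
        m = genorm_m(qtable, remaining)
        worst = m.idxmax()
        excluded.append(worst)
        remaining.remove(worst)
    return excluded + remaining


def _normalization_factors(wide: pd.DataFrame, references: list[str]) -> pd.Series:
    logq = np.log(wide[references].to_numpy())
    nf = np.exp(logq.mean(axis=1))
    nf = nf / np.exp(np.mean(np.log(nf)))  # rescale to geometric mean 1
    return pd.Series(nf, index=wide.index, name="normalization_factor")


def pairwise_variation(qtable: pd.DataFrame, ranking: list[str] | None = None) -> pd.Series:
    """geNorm pairwise variation V(n/n+1) between successive reference sets.

    V(n/n+1) is the standard deviation across samples of log2(NF_n/NF_{n+1})
    where NF_n uses the n most stable genes. Small V means adding the next
    gene changes normalization little.
    """
    wide = _wide_quantities(qtable)
    if ranking is None:
        ranking = genorm_ranking(qtable)
    best_first = list(reversed(ranking))
    out = {}
    for n in range(2, len(best_first)):
        nf_n = _normalization_factors(wide, best_first[:n])
        nf_n1 = _normalization_factors(wide, best_first[: n + 1])
        out[f"V{n}/{n + 1}"] = float(np.std(np.log2(nf_n / nf_n1), ddof=1))
    return pd.Series(out, name="V")


@dataclass
class GeNormResult:
    m_values: pd.Series
    ranking: list[str]
    pairwise_v: pd.Series
    normalization_factor: pd.Series
    reference_gene_set: list[str]


def normalization_and_fold_change(
    qtable: pd.DataFrame,
    reference_genes: list[str],
    control_group: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Normalize quantities to the reference set and compute group fold changes.

    The per-sample normalization factor is the geometric mean of the
    reference genes' quantities, rescaled to overall geometric mean 1;
    normalized quantity = quantity / NF. Fold change per (gene, group) is
    the group geometric mean over the control group's geometric mean.
    Works with a single reference gene (e.g. Hprt alone) or a multi-gene
    geNorm set.
    """
    if not reference_genes:
        raise ValueError("reference gene set is empty")
    wide = _wide_quantities(qtable)
    missing = [g for g in reference_genes if g not in wide.columns]
    if missing:
        raise ValueError(f"reference genes absent from table: {missing}")
    groups = qtable.drop_duplicates("sample").set_index("sample")["group"]
    if control_group not in set(groups):
        raise ValueError(f"control group {control_group!r} not present")

    nf = _normalization_factors(wide, list(reference_genes))
    normalized = wide.div(nf, axis=0)

    norm_long = (
        normalized.reset_index()
        .melt(id_vars="sample", var_name="gene", value_name="normalized_quantity")
        .merge(groups.rename("group"), left_on="sample", right_index=True)
    )
    norm_long["normalization_factor"] = norm_long["sample"].map(nf)

    def geomean(x):
        return np.exp(np.mean(np.log(x)))

    grp_means = (
        norm_long.groupby(["gene", "group"])["normalized_quantity"]
        .apply(geomean)
        .rename("geomean")
        .reset_index()
    )
    ctrl = grp_means[grp_means["group"] == control_group].set_index("gene")["geomean"]
    grp_means["fold_change"] = grp_means.apply(
        lambda r: r["geomean"] / ctrl[r["gene"]], axis=1
    )
    return norm_long, grp_means
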