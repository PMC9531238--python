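"""Count normalization, low-expression filtering, and differential expression.

Counts are modelled as negative binomial with variance mu + phi*mu**2 (the
DESeq2/edgeR parameterization). Differential expression is a Wald test on the
log2 fold change of library-size-normalized group means, with a common
dispersion estimated by averaging per-feature method-of-moments estimates
across all features. Thresholds follow the strict-inequality convention:
|log2FC| > 1 and P < 0.05 for significance, mean RPM >= 0.05 / TPM >= 1 for
retention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "normalize",
    "low_expression_filter",
    "nb_de_test",
    "call_status",
    "ddct",
]

VALID_KINDS = ("miRNA", "gene")
VALID_GROUPS = ("control", "treated")


@dataclass
class CountMatrix:
    """Integer feature x sample count matrix with group labels.

    Parameters
    ----------
    counts : DataFrame
        Features in rows (index = feature ids), samples in columns.
    feature_kind : str
        ``"miRNA"`` or ``"gene"``.
    groups : Series
        Maps sample id -> ``"control"`` | ``"treated"``.
    lengths : Series, optional
        Feature length in bp; required for ``feature_kind == "gene"``
        (TPM needs it).
    """

    counts: pd.DataFrame
    feature_kind: str
    groups: pd.Series
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.feature_kind not in VALID_KINDS:
            raise ValueError(f"feature_kind must be one of {VALID_KINDS}")
        arr = self.counts.to_numpy()
        if arr.size and (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        self.groups = self.groups.reindex(self.counts.columns)
        if self.groups.isna().any():
            missing = list(self.counts.columns[self.groups.isna()])
            raise ValueError(f"samples missing a group label: {missing}")
        bad = set(self.groups) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in VALID_GROUPS:
            if not (self.groups == g).any():
                raise ValueError(f"group {g!r} has no samples")
        if self.feature_kind == "gene":
            if self.lengths is None:
                raise ValueError("gene count matrices require feature lengths")
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any() or (self.lengths <= 0).any():
                raise ValueError("lengths must be positive for every gene")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


@dataclass
class NormalizedMatrix:
    """Normalized expression values; ``unit`` is ``"TPM"`` or ``"RPM"``."""

    values: pd.DataFrame
    unit: str


def normalize(matrix: CountMatrix, unit: str) -> NormalizedMatrix:
    """Normalize counts to TPM (length+depth) or RPM (depth only).

    TPM_gs = 1e6 * (c_gs / L_g) / sum_h (c_hs / L_h)
    RPM_gs = 1e6 * c_gs / sum_h c_hs

    An all-zero sample column stays all-zero.
    """
    unit = unit.upper()
    if unit not in ("TPM", "RPM"):
        raise ValueError("unit must be 'TPM' or 'RPM'")
    counts = matrix.counts.astype(float)
    if unit == "TPM":
        if matrix.lengths is None:
            raise ValueError("TPM normalization requires feature lengths")
        rate = counts.div(matrix.lengths.astype(float), axis=0)
    else:
        rate = counts
    colsum = rate.sum(axis=0)
    # avoid 0/0 for empty libraries; those columns stay zero
    safe = colsum.replace(0.0, 1.0)
    values = rate.div(safe, axis=1) * 1e6
    return NormalizedMatrix(values=values, unit=unit)


def low_expression_filter(
    norm: NormalizedMatrix, rpm_min: float = 0.05, tpm_min: float = 1.0
) -> list[str]:
    """Return features whose mean normalized value across all samples clears
    the unit-appropriate threshold (RPM >= 0.05, TPM >= 1; boundary kept).

    Features below the threshold are the ``low_expression`` set.
    """
    threshold = tpm_min if norm.unit == "TPM" else rpm_min
    means = norm.values.mean(axis=1)
    return list(means.index[means >= threshold])


def _normalized_counts(matrix: CountMatrix) -> pd.DataFrame:
    lib = matrix.counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        zero = list(lib.index[lib == 0])
        raise ValueError(f"samples with all-zero library size: {zero}")
    size_factors = lib / lib.mean()
    return matrix.counts.astype(float).div(size_factors, axis=1)


def nb_de_test(
    matrix: CountMatrix,
    retained: list[str] | None = None,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Negative-binomial Wald test of treated vs control per feature.

    Per feature: library-size-normalized (total-count size factors) group
    means m1 (control), m2 (treated); log2fc = log2((m2+c)/(m1+c)) with
    pseudocount c; the dispersion is a single common value -- the mean over
    features of per-feature method-of-moments estimates pooled across the two
    groups -- floored at ``dispersion_floor``. The Wald z is log2fc over its
    delta-method standard error, with a two-sided normal p-value.

    Returns a DataFrame indexed by feature id with columns
    ``base_mean``, ``log2fc``, ``p_value``.
    """
    ctrl = matrix.samples_in("control")
    trt = matrix.samples_in("treated")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("nb_de_test requires >= 2 samples per group")
    norm = _normalized_counts(matrix)
    if retained is not None:
        norm = norm.loc[[f for f in matrix.feature_ids if f in set(retained)]]
    y1 = norm[ctrl].to_numpy()
    y2 = norm[trt].to_numpy()
    m1 = y1.mean(axis=1)
    m2 = y2.mean(axis=1)
    v1 = y1.var(axis=1, ddof=1)
    v2 = y2.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        phi_g1 = np.where(m1 > 0, (v1 - m1) / m1**2, np.nan)
        phi_g2 = np.where(m2 > 0, (v2 - m2) / m2**2, np.nan)
    phi_feat = np.nanmean(np.vstack([phi_g1, phi_g2]), axis=0)
    phi = float(np.nanmean(phi_feat)) if np.isfinite(phi_feat).any() else 0.0
    phi = max(phi, dispersion_floor)

    log2fc = np.log2((m2 + pseudocount) / (m1 + pseudocount))
    var_m1 = (m1 + phi * m1**2) / y1.shape[1]
    var_m2 = (m2 + phi * m2**2) / y2.shape[1]
    se = np.sqrt(var_m2 / (m2 + pseudocount) ** 2 + var_m1 / (m1 + pseudocount) ** 2) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, np.where(log2fc == 0, 0.0, np.inf * np.sign(log2fc)))
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "base_mean": (m1 + m2) / 2.0,
            "log2fc": log2fc,
            "p_value": np.clip(p, 0.0, 1.0),
        },
        index=norm.index.rename("feature_id"),
    )


def call_status(
    results: pd.DataFrame,
    lfc_min: float = 1.0,
    p_max: float = 0.05,
    low_expression: set[str] | None = None,
) -> pd.DataFrame:
    """Assign up/down/ns/low_expression status from (log2fc, p_value).

    Strict inequalities: ``up`` iff log2fc > lfc_min and p < p_max;
    ``down`` iff log2fc < -lfc_min and p < p_max; otherwise ``ns``.
    Accepts any table carrying ``log2fc`` and ``p_value`` columns, so
    externally published (log2fc, p) tables can be re-called.
    """
    out = results.copy()
    lfc = out["log2fc"].to_numpy(dtype=float)
    p = out["p_value"].to_numpy(dtype=float)
    status = np.where(
        (lfc > lfc_min) & (p < p_max),
        "up",
        np.where((lfc < -lfc_min) & (p < p_max), "down", "ns"),
    ).astype(object)
    if low_expression:
        mask = out.index.isin(low_expression)
        status[mask] = "low_expression"
    out["status"] = status
    return out


def ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    fold = 2 ** -((Ct_target,treated - Ct_ref,treated)
                  - (Ct_target,control - Ct_ref,control))
    """
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    dct_treated = ct_target_treated - ct_ref_treated
    dct_control = ct_target_control - ct_ref_control
    return float(2.0 ** -(dct_treated - dct_control))
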