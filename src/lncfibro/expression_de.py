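"""RPKM quantification and UUO-vs-Sham differential expression calls.

Expression is quantified as RPKM (reads per kilobase of exon per million
reads), rpkm = c * 1e9 / (N * L) with N the column sum of the analyzed
matrix. Transcripts are called differentially expressed when
|log2FC| >= 1 (inclusive) and a two-sided Welch t-test on log2(RPKM +
pseudocount) gives p < 0.05 (strict). No multiple-testing correction by
default; Benjamini-Hochberg is available as an option.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .models import DERecord, ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 0.25


def compute_rpkm(matrix: ExpressionMatrix, lengths: Mapping[str, int]) -> pd.DataFrame:
    """rpkm[i, j] = c[i, j] * 1e9 / (N[j] * L[i])."""
    missing = [t for t in matrix.counts.index if t not in lengths]
    if missing:
        raise ValueError(f"missing exonic length for transcript(s): {missing[:5]}")
    L = np.array([lengths[t] for t in matrix.counts.index], dtype=float)
    if (L <= 0).any():
        raise ValueError("non-positive transcript length")
    N = matrix.library_sizes.to_numpy(dtype=float)
    if (N <= 0).any():
        raise ValueError("sample with zero library size")
    vals = matrix.counts.to_numpy(dtype=float) * 1e9 / (N[None, :] * L[:, None])
    return pd.DataFrame(vals, index=matrix.counts.index, columns=matrix.counts.columns)


def log2_fold_change(
    mean_case: float, mean_control: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    return float(np.log2((mean_case + pseudocount) / (mean_control + pseudocount)))


def _welch(case: np.ndarray, control: np.ndarray) -> float:
    """Two-sided Welch t-test p-value, never NaN.

    Both groups constant: p = 1 when the constants agree, p = 0 otherwise
    (infinite evidence at zero noise).
    """
    v1, v2 = case.var(ddof=1), control.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        return 1.0 if case.mean() == control.mean() else 0.0
    t, p = stats.ttest_ind(case, control, equal_var=False)
    return float(p)


def per_transcript_test(
    rpkm_case: np.ndarray,
    rpkm_control: np.ndarray,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Welch t-test on log2(RPKM + pseudocount); two-sided."""
    case = np.asarray(rpkm_case, dtype=float)
    control = np.asarray(rpkm_control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise ValueError("each group needs at least 2 values")
    return _welch(np.log2(case + pseudocount), np.log2(control + pseudocount))


def _vectorized_welch(case: np.ndarray, control: np.ndarray) -> np.ndarray:
    """Row-wise Welch p-values for (transcripts x replicates) arrays."""
    n1, n2 = case.shape[1], control.shape[1]
    m1, m2 = case.mean(axis=1), control.mean(axis=1)
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0.0
    p[degenerate & (m1 == m2)] = 1.0
    p[degenerate & (m1 != m2)] = 0.0
    return p


def call_de(
    matrix: ExpressionMatrix,
    lengths: Mapping[str, int],
    lfc_cutoff: float = 1.0,
    p_cutoff: float = 0.05,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    bh_correction: bool = False,
) -> list[DERecord]:
    """Call DE for every transcript of a single-compartment matrix.

    Significant iff |log2FC| >= lfc_cutoff AND p < p_cutoff. Direction is
    up/down by the sign of log2FC among significant calls, none otherwise.
    """
    compartments = set(matrix.samples["compartment"])
    if len(compartments) != 1:
        raise ValueError(f"matrix mixes compartments {sorted(compartments)}; call one at a time")
    uuo = matrix.samples.index[matrix.samples["condition"] == "UUO"]
    sham = matrix.samples.index[matrix.samples["condition"] == "Sham"]
    if len(uuo) < 2 or len(sham) < 2:
        raise ValueError("need >= 2 replicates per condition")

    rpkm = compute_rpkm(matrix, lengths)
    case = rpkm[list(uuo)].to_numpy()
    control = rpkm[list(sham)].to_numpy()
    mean_case, mean_control = case.mean(axis=1), control.mean(axis=1)
    lfc = np.log2((mean_case + pseudocount) / (mean_control + pseudocount))
    p = _vectorized_welch(np.log2(case + pseudocount), np.log2(control + pseudocount))
    p_eff = p
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        p_eff = multipletests(p, method="fdr_bh")[1]

    records: list[DERecord] = []
    for i, tid in enumerate(rpkm.index):
        significant = bool(abs(lfc[i]) >= lfc_cutoff and p_eff[i] < p_cutoff)
        if significant:
            direction = "up" if lfc[i] > 0 else "down"
        else:
            direction = "none"
        records.append(
            DERecord(
                transcript_id=tid,
                mean_rpkm_uuo=float(mean_case[i]),
                mean_rpkm_sham=float(mean_control[i]),
                log2fc=float(lfc[i]),
                p_value=float(p_eff[i]),
                direction=direction,
                significant=significant,
            )
        )
    return records


def de_summary(records: list[DERecord]) -> dict[str, int]:
    n_up = sum(1 for r in records if r.significant and r.direction == "up")
    n_down = sum(1 for r in records if r.significant and r.direction == "down")
    return {"n_tested": len(records), "n_up": n_up, "n_down": n_down}
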