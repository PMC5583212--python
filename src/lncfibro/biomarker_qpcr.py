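"""Tissue-urine concordance and 2^-ddCt qPCR quantification.

Urinary biomarker candidates are transcripts significantly changed in BOTH
renal tissue and urine with the same direction. qPCR fold changes follow the
Livak 2^-ddCt construction: dCt = Ct_target - Ct_reference per sample,
ddCt = dCt - mean(dCt over the calibrator group), fold = 2^-ddCt; group
significance is a two-sided Welch t-test on dCt. Urine tables are normalized
to the cel-miR-39 spike-in instead of an endogenous reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import DERecord

SPIKE_IN_ID = "cel-miR-39"


@dataclass(frozen=True)
class ConcordanceRecord:
    transcript_id: str
    tissue_direction: str
    urine_direction: str
    concordant: bool


@dataclass
class QpcrRecord:
    target: str
    sample_id: str
    group: str
    ct_target: float
    ct_reference: float
    delta_ct: float
    delta_delta_ct: float
    fold: float


def concordant_biomarkers(
    tissue_de: list[DERecord], urine_de: list[DERecord]
) -> list[ConcordanceRecord]:
    """One record per transcript significant in both compartments.

    ``concordant`` is true when the directions agree; only concordant
    records are biomarker candidates, but discordant ones are reported too.
    """
    tissue_sig = {r.transcript_id: r.direction for r in tissue_de if r.significant}
    urine_sig = {r.transcript_id: r.direction for r in urine_de if r.significant}
    records = []
    for tid in sorted(set(tissue_sig) & set(urine_sig)):
        t_dir, u_dir = tissue_sig[tid], urine_sig[tid]
        records.append(ConcordanceRecord(tid, t_dir, u_dir, t_dir == u_dir))
    return records


def concordance_summary(records: list[ConcordanceRecord]) -> dict[str, int]:
    up = sum(1 for r in records if r.concordant and r.tissue_direction == "up")
    down = sum(1 for r in records if r.concordant and r.tissue_direction == "down")
    return {"n_overlapping": len(records), "n_concordant_up": up, "n_concordant_down": down}


def _validate_qpcr_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if (table["ct"] < 0).any():
        raise ValueError("negative Ct value in qPCR table")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str = "Sham",
) -> tuple[list[QpcrRecord], pd.DataFrame]:
    """Livak 2^-ddCt quantification for every non-reference target.

    ``table`` is long-format (sample_id, group, gene, ct). Returns the
    per-sample records and a per-target summary with group mean/SD of folds,
    the geometric-mean fold, and a Welch t-test p-value on dCt between the
    two groups.
    """
    table = _validate_qpcr_table(table)
    ref = table[table["gene"] == reference_gene].set_index("sample_id")["ct"]
    samples = table["sample_id"].unique()
    missing_ref = [s for s in samples if s not in ref.index]
    if missing_ref:
        raise ValueError(f"missing reference Ct ({reference_gene}) for samples: {missing_ref}")

    groups = table.drop_duplicates("sample_id").set_index("sample_id")["group"]
    n_cal = int((groups == calibrator_group).sum())
    if n_cal < 2:
        raise ValueError(f"calibrator group {calibrator_group!r} needs >= 2 samples, has {n_cal}")

    records: list[QpcrRecord] = []
    rows = []
    targets = [g for g in table["gene"].unique() if g != reference_gene]
    for target in targets:
        sub = table[table["gene"] == target]
        missing = [s for s in samples if s not in set(sub["sample_id"])]
        if missing:
            raise ValueError(f"target {target}: missing Ct for samples {missing}")
        dct = {
            row.sample_id: row.ct - ref[row.sample_id] for row in sub.itertuples()
        }
        cal_mean = float(np.mean([dct[s] for s in samples if groups[s] == calibrator_group]))
        target_records = []
        for row in sub.itertuples():
            ddct = dct[row.sample_id] - cal_mean
            target_records.append(
                QpcrRecord(
                    target=target,
                    sample_id=row.sample_id,
                    group=row.group,
                    ct_target=float(row.ct),
                    ct_reference=float(ref[row.sample_id]),
                    delta_ct=float(dct[row.sample_id]),
                    delta_delta_ct=float(ddct),
                    fold=float(2.0 ** (-ddct)),
                )
            )
        records.extend(target_records)

        dct_cal = np.array([dct[s] for s in samples if groups[s] == calibrator_group])
        dct_other = np.array([dct[s] for s in samples if groups[s] != calibrator_group])
        if dct_other.size >= 2:
            if dct_cal.var(ddof=1) == 0.0 and dct_other.var(ddof=1) == 0.0:
                p = 1.0 if dct_cal.mean() == dct_other.mean() else 0.0
            else:
                p = float(stats.ttest_ind(dct_other, dct_cal, equal_var=False)[1])
        else:
            p = float("nan")
        for group_name, members in (
            (calibrator_group, [r for r in target_records if r.group == calibrator_group]),
            ("treated", [r for r in target_records if r.group != calibrator_group]),
        ):
            folds = np.array([r.fold for r in members])
            if folds.size == 0:
                continue
            rows.append(
                {
                    "target": target,
                    "group": members[0].group,
                    "n": folds.size,
                    "mean_fold": float(folds.mean()),
                    "sd_fold": float(folds.std(ddof=1)) if folds.size > 1 else 0.0,
                    "geo_mean_fold": float(2.0 ** np.mean(np.log2(folds))),
                    "p_value": p,
                    "reference_gene": reference_gene,
                }
            )
    return records, pd.DataFrame(rows)


def spike_in_normalize(
    table: pd.DataFrame,
    spike_id: str = SPIKE_IN_ID,
    calibrator_group: str = "Sham",
) -> tuple[list[QpcrRecord], pd.DataFrame]:
    """ddCt with the exogenous spike-in as the reference (urine samples).

    Errors listing the offending samples when the spike is missing anywhere.
    """
    table = _validate_qpcr_table(table)
    spiked = set(table.loc[table["gene"] == spike_id, "sample_id"])
    missing = sorted(set(table["sample_id"]) - spiked)
    if missing:
        raise ValueError(f"spike-in {spike_id} missing for samples: {missing}")
    records, summary = delta_delta_ct(table, reference_gene=spike_id, calibrator_group=calibrator_group)
    if not summary.empty:
        summary["spike_normalized"] = True
    return records, summary


def qpcr_records_to_frame(records: list[QpcrRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "target": [r.target for r in records],
            "sample_id": [r.sample_id for r in records],
            "group": [r.group for r in records],
            "ct_target": [r.ct_target for r in records],
            "ct_reference": [r.ct_reference for r in records],
            "delta_ct": [r.delta_ct for r in records],
            "delta_delta_ct": [r.delta_delta_ct for r in records],
            "fold": [r.fold for r in records],
        }
    )
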