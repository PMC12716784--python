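"""Gland-specificity calling by fold-change threshold.

A transcript is called gland-specific when its expression is at least
16-fold higher (log2FC >= 4) than the anterior-abdomen control in *all
four* gland tissues.  The comparison is inclusive and exact: the rule is
a definition, not an estimate, so no epsilon is applied — a log2FC of
3.9999999 produced by upstream rounding fails, and exactly 4.0 passes.

The classical stricter cut-off of 64-fold (log2FC >= 6) used in earlier
work is available by passing ``threshold_log2=6``.
"""

from __future__ import annotations

import pandas as pd

from stinkgland.design import SampleDesign
from stinkgland.expression import apply_pseudocount, compute_depth, compute_log2fc

DEFAULT_THRESHOLD_LOG2 = 4.0

N_GLAND_TISSUES = 4


def call_gland_specific(
    fc: pd.DataFrame, threshold_log2: float = DEFAULT_THRESHOLD_LOG2
) -> pd.DataFrame:
    """One specificity call per transcript.

    Parameters
    ----------
    fc
        Fold-change table: transcript_id index, exactly four gland
        columns of log2 fold change vs control.
    threshold_log2
        Inclusive log2 fold-change threshold (default 4, i.e. FC >= 16).

    Returns
    -------
    DataFrame with columns ``transcript_id``, ``is_gland_specific``,
    ``tissues_passing`` (0–4) and ``min_log2fc`` (the minimum over the
    four gland tissues, i.e. the binding constraint).
    """
    if fc.shape[1] != N_GLAND_TISSUES:
        raise ValueError(
            f"fold-change table must have exactly {N_GLAND_TISSUES} gland columns, "
            f"got {fc.shape[1]}"
        )
    passing = (fc >= threshold_log2).sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "transcript_id": fc.index,
            "is_gland_specific": (passing == N_GLAND_TISSUES).to_numpy(),
            "tissues_passing": passing.to_numpy(),
            "min_log2fc": fc.min(axis=1).to_numpy(),
        }
    )


def near_miss_report(
    fc: pd.DataFrame,
    threshold_log2: float = DEFAULT_THRESHOLD_LOG2,
    min_passing: int = 3,
) -> pd.DataFrame:
    """Non-specific transcripts that pass in at least ``min_passing`` tissues.

    Flags candidates that just fail the all-four rule — e.g. a
    transcript at log2FC >= 4 in three tissues but 3.1 in the fourth —
    sorted by descending ``min_log2fc`` so the closest miss comes first.
    The report lists the failing tissues with their fold changes.
    """
    if not 0 <= min_passing <= N_GLAND_TISSUES:
        raise ValueError("min_passing must be between 0 and 4")
    calls = call_gland_specific(fc, threshold_log2).set_index("transcript_id")
    near = calls[(~calls["is_gland_specific"]) & (calls["tissues_passing"] >= min_passing)]
    rows = []
    for tid in near.index:
        row = fc.loc[tid]
        failing = row[row < threshold_log2]
        rows.append(
            {
                "transcript_id": tid,
                "tissues_passing": int(near.loc[tid, "tissues_passing"]),
                "min_log2fc": float(near.loc[tid, "min_log2fc"]),
                "failing_tissues": ";".join(
                    f"{t}={v:.4f}" for t, v in failing.items()
                ),
            }
        )
    report = pd.DataFrame(
        rows, columns=["transcript_id", "tissues_passing", "min_log2fc", "failing_tissues"]
    )
    return report.sort_values(
        "min_log2fc", ascending=False, kind="stable"
    ).reset_index(drop=True)


def call_from_counts(
    counts: pd.DataFrame,
    catalog: pd.DataFrame,
    design: SampleDesign,
    threshold_log2: float = DEFAULT_THRESHOLD_LOG2,
    read_length_bp: int = 38,
) -> pd.DataFrame:
    """Convenience composition: pseudocount -> depth -> log2FC -> call."""
    pseudo = apply_pseudocount(counts)
    depth = compute_depth(pseudo, catalog, read_length_bp=read_length_bp)
    fc = compute_log2fc(depth, design)
    return call_gland_specific(fc, threshold_log2=threshold_log2)
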