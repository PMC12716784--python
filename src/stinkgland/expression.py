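"""Read-depth normalization and gland-vs-control log2 fold changes.

The normalization is the per-transcript coverage-like "reads depth"

    depth = (mapped reads x read_length_bp) / transcript length in bp

with ``read_length_bp = 38`` by default, matching the sequencing read
length of the original gland libraries.  Zero-count cells receive a
pseudocount of one read *before* depth computation, so every transcript
keeps a finite log fold change.  The fold change of a transcript in a
gland sample is

    log2FC = log2(depth_gland / depth_control)

in which both transcript length and read length cancel, so log2FC
depends only on the (pseudocounted) read counts.  The stage order is
fixed: longest-isoform selection -> pseudocount -> depth -> log2FC.

Count matrices are DataFrames indexed by transcript_id with one column
per sample label.  No between-sample library-size normalization is
applied anywhere: the rule operates on raw per-transcript ratios.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from stinkgland.catalog import transcript_lengths
from stinkgland.design import SampleDesign

DEFAULT_READ_LENGTH_BP = 38


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts must be non-negative integers."""
    values = counts.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values)):
            raise ValueError("count matrix contains non-integral values")
    if values.size and (values < 0).any():
        raise ValueError("count matrix contains negative values")
    return counts


def apply_pseudocount(counts: pd.DataFrame) -> pd.DataFrame:
    """Replace zero cells by one read; leave non-zero cells untouched.

    This keeps transcripts with no mapped reads in a sample informative
    in the fold-change step instead of producing infinities.
    """
    validate_counts(counts)
    return counts.mask(counts == 0, 1)


def compute_depth(
    counts: pd.DataFrame,
    catalog: pd.DataFrame,
    read_length_bp: int = DEFAULT_READ_LENGTH_BP,
) -> pd.DataFrame:
    """Per-cell depth = (count * read_length_bp) / length_bp.

    Requires the pseudocount to have been applied already (all cells
    >= 1); a zero cell is rejected with a pointer to
    :func:`apply_pseudocount` so the fixed stage order cannot be
    violated silently.
    """
    if read_length_bp <= 0:
        raise ValueError("read_length_bp must be positive")
    validate_counts(counts)
    if (counts.to_numpy() == 0).any():
        raise ValueError(
            "count matrix contains zero cells; apply_pseudocount() first"
        )
    lengths = transcript_lengths(catalog)
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"transcript {missing[0]!r} not present in catalog")
    lens = lengths.reindex(counts.index).to_numpy(dtype=float)
    depth = counts.to_numpy(dtype=float) * float(read_length_bp) / lens[:, None]
    return pd.DataFrame(depth, index=counts.index, columns=counts.columns)


def compute_log2fc(depths: pd.DataFrame, design: SampleDesign) -> pd.DataFrame:
    """log2(gland depth / control depth), one column per gland sample.

    Columns follow the stable gland order of the design (female
    abdominal, female prothoracic, male abdominal, male prothoracic).
    """
    control = design.control_sample
    if control not in depths.columns:
        raise ValueError(f"control sample {control!r} missing from depth matrix")
    if (depths.to_numpy() <= 0).any():
        raise ValueError("depth matrix must be strictly positive (pseudocount first)")
    gland_cols = [s for s in design.gland_samples if s in depths.columns]
    if len(gland_cols) < len(design.gland_samples):
        missing = set(design.gland_samples) - set(gland_cols)
        raise ValueError(f"gland samples missing from depth matrix: {sorted(missing)}")
    ref = depths[control].to_numpy()
    fc = np.log2(depths[gland_cols].to_numpy() / ref[:, None])
    return pd.DataFrame(fc, index=depths.index, columns=gland_cols)


# ---------------------------------------------------------------------------
# table IO


def read_counts_tsv(path: str | Path, decimal: str = ".") -> pd.DataFrame:
    """Read a transcripts x samples count table.

    First column is the transcript_id; remaining columns are samples.
    ``decimal=","`` accepts decimal-comma locales in numeric columns.
    """
    counts = pd.read_csv(path, sep="\t", index_col=0, decimal=decimal)
    counts.index = counts.index.astype(str).str.strip()
    return validate_counts(counts)


def write_matrix_tsv(
    matrix: pd.DataFrame, path: str | Path, float_decimals: int | None = None
) -> None:
    """Write a transcripts x samples matrix; reports round to 4 decimals."""
    fmt = None if float_decimals is None else f"%.{float_decimals}f"
    matrix.to_csv(path, sep="\t", index_label="transcript_id", float_format=fmt)
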