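"""Transcript catalogs: transcripts with lengths, grouped into genes.

A catalog is a plain :class:`pandas.DataFrame` with columns

    gene_id, transcript_id, length_bp, annotation_version

one row per transcript.  ``transcript_id`` is unique; every transcript
belongs to exactly one gene; ``length_bp`` is a positive integer.
Expression analysis works on the longest isoform per gene, so the usual
first step is :func:`select_longest_isoform`.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

CATALOG_COLUMNS = ["gene_id", "transcript_id", "length_bp", "annotation_version"]


def validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    """Check catalog invariants; return the catalog unchanged.

    Raises
    ------
    ValueError
        If a required column is missing, a length is non-positive, a
        transcript_id is duplicated, or a transcript maps to more than
        one gene.
    """
    missing = [c for c in CATALOG_COLUMNS if c not in catalog.columns]
    if missing:
        raise ValueError(f"catalog missing columns: {missing}")
    if len(catalog) == 0:
        return catalog
    if (catalog["length_bp"] <= 0).any():
        bad = catalog.loc[catalog["length_bp"] <= 0, "transcript_id"].iloc[0]
        raise ValueError(f"non-positive length_bp for transcript {bad!r}")
    dup = catalog["transcript_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"duplicate transcript_id {catalog.loc[dup, 'transcript_id'].iloc[0]!r}"
        )
    # transcript_id unique implies one gene per transcript row-wise; nothing
    # further to check.
    return catalog


def select_longest_isoform(catalog: pd.DataFrame) -> pd.DataFrame:
    """Keep one transcript per gene: the longest isoform.

    Length ties are broken by the lexicographically smallest
    transcript_id, so the result is deterministic.
    """
    validate_catalog(catalog)
    if len(catalog) == 0:
        return catalog.copy()
    ranked = catalog.sort_values(
        ["gene_id", "length_bp", "transcript_id"],
        ascending=[True, False, True],
    )
    kept = ranked.drop_duplicates("gene_id", keep="first")
    return kept.sort_index().reset_index(drop=True)


def transcript_lengths(catalog: pd.DataFrame) -> pd.Series:
    """length_bp indexed by transcript_id."""
    return catalog.set_index("transcript_id")["length_bp"]


def write_catalog_tsv(catalog: pd.DataFrame, path: str | Path) -> None:
    validate_catalog(catalog)
    catalog[CATALOG_COLUMNS].to_csv(path, sep="\t", index=False)


def read_catalog_tsv(path: str | Path) -> pd.DataFrame:
    catalog = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "transcript_id": str})
    catalog["length_bp"] = catalog["length_bp"].astype(int)
    return validate_catalog(catalog)


def read_catalog_fasta(
    path: str | Path, annotation_version: str = "unknown"
) -> pd.DataFrame:
    """Build a catalog from a transcript FASTA; lengths are sequence lengths.

    The gene for a transcript is taken from a ``gene=`` key in the
    description if present, otherwise the transcript id itself (i.e. a
    single-isoform catalog).
    """
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene = rec.id
        for tok in rec.description.split():
            if tok.startswith("gene="):
                gene = tok[len("gene=") :]
        rows.append(
            {
                "gene_id": gene,
                "transcript_id": rec.id,
                "length_bp": len(rec.seq),
                "annotation_version": annotation_version,
            }
        )
    return validate_catalog(pd.DataFrame(rows, columns=CATALOG_COLUMNS))
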