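"""RNAi-screen phenotype vocabulary: gland morphology and volatiles.

Knock-down gland morphology is recorded as exactly one of seven
controlled categories (or wild-type-like):

    I    secretion color darker
    II   secretion color lighter
    III  irregular reservoir size
    IV   less secretion
    V    colorless secretion
    VI   melanized gland content
    VII  size decreased

Gland secretions are assayed by GC-MS for four volatiles in two gland
regions (abdominal and prothoracic): the para-benzoquinones MBQ
(2-methyl-1,4-benzoquinone) and EBQ (2-ethyl-1,4-benzoquinone), and the
alkenes 1-C15 (1-pentadecene) and 1-C17 (1-heptadecene).  The two
benzoquinones behave together, as do the two alkenes, so calls are
summarized at compound-class level: a class counts as "reduced" in a
region only when *every* compound of the class falls below a fraction of
the wild-type reference peak area (default 10%; the screen's "strong
reduction" is semi-quantitative, so the threshold is explicit and
configurable, and reports echo it).

A phenotype table is a DataFrame with one row per gene: ``gene_id``,
``morphology``, and one status column ("normal"/"reduced") per
region x class cell, e.g. ``abdominal_benzoquinone``.  Tables can be
ingested pre-classified (the screen's categorical tables) or derived
from peak areas via :func:`classify_volatiles`; both paths produce the
same shape.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MORPHOLOGY_CATEGORIES = ("I", "II", "III", "IV", "V", "VI", "VII")
WILD_TYPE = "wild-type-like"
MORPHOLOGY_LABELS = MORPHOLOGY_CATEGORIES + (WILD_TYPE,)

REGIONS = ("abdominal", "thoracic")
COMPOUND_CLASSES: dict[str, tuple[str, ...]] = {
    "benzoquinone": ("MBQ", "EBQ"),
    "alkene": ("1-C15", "1-C17"),
}
COMPOUNDS = COMPOUND_CLASSES["benzoquinone"] + COMPOUND_CLASSES["alkene"]

#: Status columns of a phenotype table, fixed order.
STATUS_COLUMNS = tuple(
    f"{region}_{cls}" for region in REGIONS for cls in COMPOUND_CLASSES
)

DEFAULT_REDUCTION_FRACTION = 0.10


def validate_phenotypes(records: pd.DataFrame) -> pd.DataFrame:
    if "gene_id" not in records.columns or "morphology" not in records.columns:
        raise ValueError("phenotype table needs gene_id and morphology columns")
    bad = ~records["morphology"].isin(MORPHOLOGY_LABELS)
    if bad.any():
        raise ValueError(
            f"unknown morphology label {records.loc[bad, 'morphology'].iloc[0]!r}"
        )
    return records


def tabulate_morphology(records: pd.DataFrame) -> pd.DataFrame:
    """Counts and integer percentages per morphology category.

    Percentages are computed over genes with a non-wild-type morphology
    and rounded to the nearest integer percent (so they can sum to
    100 +/- rounding slack); raw counts are retained alongside.
    """
    validate_phenotypes(records)
    if len(records) == 0:
        raise ValueError("phenotype table is empty")
    counts = records["morphology"].value_counts()
    counts = counts.reindex(MORPHOLOGY_LABELS, fill_value=0)
    phenotypic = int(counts[list(MORPHOLOGY_CATEGORIES)].sum())
    table = pd.DataFrame({"morphology": MORPHOLOGY_LABELS, "count": counts.to_numpy()})
    pct = []
    for label, n in zip(table["morphology"], table["count"]):
        if label == WILD_TYPE or phenotypic == 0:
            pct.append(pd.NA)
        else:
            pct.append(int(round(100.0 * n / phenotypic)))
    table["percent"] = pct
    return table


def classify_volatiles(
    profile: pd.DataFrame,
    reference: pd.DataFrame,
    reduction_fraction: float = DEFAULT_REDUCTION_FRACTION,
) -> dict[str, str]:
    """Call each region x compound-class cell "normal" or "reduced".

    ``profile`` and ``reference`` are region x compound peak-area
    tables (index: abdominal/thoracic; columns: MBQ, EBQ, 1-C15, 1-C17;
    arbitrary units, non-negative).  A class is reduced in a region iff
    every compound of the class has area strictly below
    ``reduction_fraction x reference`` there.

    The call is monotone in ``reduction_fraction``: shrinking the
    fraction can only remove "reduced" cells.
    """
    if not 0 < reduction_fraction < 1:
        raise ValueError("reduction_fraction must lie in (0, 1)")
    for frame, name in ((profile, "profile"), (reference, "reference")):
        if (frame.loc[list(REGIONS), list(COMPOUNDS)].to_numpy() < 0).any():
            raise ValueError(f"{name} contains negative peak areas")
    status: dict[str, str] = {}
    for region in REGIONS:
        for cls, compounds in COMPOUND_CLASSES.items():
            reduced = True
            for compound in compounds:
                ref = float(reference.loc[region, compound])
                if ref <= 0:
                    raise ValueError(
                        f"reference peak area for {compound} in {region} region "
                        "must be positive"
                    )
                if float(profile.loc[region, compound]) >= reduction_fraction * ref:
                    reduced = False
            status[f"{region}_{cls}"] = "reduced" if reduced else "normal"
    return status


def summarize_volatile_categories(records: pd.DataFrame) -> dict[str, int]:
    """Gene counts per volatile-reduction category.

    Categories (a gene can fall in several; see invariants):

    - ``bq_both``: benzoquinones reduced in both gland regions;
    - ``alkene_both``: alkenes reduced in both regions *without* the
      benzoquinones also being reduced in both;
    - ``all_volatiles``: all four region x class cells reduced (a subset
      of ``bq_both``);
    - ``gland_specific``: some reduction, but no compound class reduced
      in both regions — the change is restricted to one gland region
      (or one region x class cell);
    - ``any_change``: at least one cell reduced.

    Invariant: all_volatiles <= bq_both <= any_change <= table size, and
    bq_both + alkene_both + gland_specific == any_change.
    """
    validate_phenotypes(records)
    missing = [c for c in STATUS_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"phenotype table missing volatile status columns: {missing}")
    reduced = records[list(STATUS_COLUMNS)].eq("reduced")
    bq_both = reduced["abdominal_benzoquinone"] & reduced["thoracic_benzoquinone"]
    alkene_both = reduced["abdominal_alkene"] & reduced["thoracic_alkene"]
    all_volatiles = reduced.all(axis=1)
    any_change = reduced.any(axis=1)
    restricted = any_change & ~bq_both & ~alkene_both
    return {
        "bq_both": int(bq_both.sum()),
        "alkene_both": int((alkene_both & ~bq_both).sum()),
        "all_volatiles": int(all_volatiles.sum()),
        "gland_specific": int(restricted.sum()),
        "any_change": int(any_change.sum()),
    }


# ---------------------------------------------------------------------------
# IO


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path, sep="\t", dtype=str)
    records["gene_id"] = records["gene_id"].str.strip()
    return validate_phenotypes(records)


def read_phenotypes_xlsx(path: str | Path, sheet: int | str = 0) -> pd.DataFrame:
    """Read a spreadsheet-format screen table with the same columns."""
    records = pd.read_excel(path, sheet_name=sheet, dtype=str)
    return validate_phenotypes(records)


def write_phenotypes_tsv(records: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(records).to_csv(path, sep="\t", index=False)
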