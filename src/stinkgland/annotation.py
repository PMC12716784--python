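"""Gene-list reconciliation across annotation versions, and overlaps.

An improved genome annotation can fuse two old gene models into one new
model, so a gene list called against the old official gene set (OGS2)
must be remapped through a many-to-one ``old id -> new id`` mapping
before it can be intersected with lists called against the new set
(OGS3).  Remapping then de-duplicating is what turns, e.g., 212 old
gene models into 208 new ones when four pairs were fused.

Identifiers (Tc_###### gene models, iB_##### screen numbers) are
treated as opaque case-sensitive strings; whitespace is trimmed on read.
Intersecting lists from different annotation versions without remapping
is the caller's responsibility to avoid — helpers here operate on lists
already expressed in a common version.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


def validate_mapping(mapping: pd.DataFrame) -> pd.DataFrame:
    """A mapping is a function: each source_id appears exactly once."""
    for col in ("source_id", "target_id"):
        if col not in mapping.columns:
            raise ValueError(f"mapping missing column {col!r}")
    dup = mapping["source_id"].duplicated()
    if dup.any():
        raise ValueError(
            f"source_id {mapping.loc[dup, 'source_id'].iloc[0]!r} mapped more than once"
        )
    return mapping


def remap_gene_list(
    genes: list[str],
    mapping: pd.DataFrame,
    on_missing: str = "keep",
) -> list[str]:
    """Replace each id by its mapping target; de-duplicate, order-stable.

    ``on_missing`` controls ids absent from the mapping: ``"keep"``
    passes them through unchanged (the default — genes annotated only in
    the new version have no old-model entry), ``"drop"`` removes them,
    ``"error"`` raises naming the first unmapped id.

    The output never exceeds the input in length, and fused pairs
    collapse to a single id at the position of their first occurrence.
    """
    if on_missing not in {"error", "keep", "drop"}:
        raise ValueError(f"unknown on_missing policy {on_missing!r}")
    validate_mapping(mapping)
    lookup = dict(zip(mapping["source_id"], mapping["target_id"]))
    out: list[str] = []
    seen: set[str] = set()
    for gene in genes:
        if gene in lookup:
            target = lookup[gene]
        elif on_missing == "keep":
            target = gene
        elif on_missing == "drop":
            continue
        else:
            raise KeyError(f"gene {gene!r} has no entry in the mapping")
        if target not in seen:
            seen.add(target)
            out.append(target)
    return out


@dataclass
class OverlapSummary:
    """Sizes and membership structure of 2–3 named gene lists.

    ``membership`` is a DataFrame indexed by gene_id with one boolean
    column per list; every reported size is recomputable from it, and
    the inclusion–exclusion identities hold exactly by construction.
    """

    names: list[str]
    sizes: dict[str, int]
    pairwise: dict[tuple[str, str], int]
    triple: int | None
    union: int
    membership: pd.DataFrame

    def venn_counts(self) -> dict[str, int]:
        """Exclusive region counts keyed by '+'-joined member names."""
        regions: dict[str, int] = {}
        m = self.membership
        for mask, group in m.groupby(list(m.columns)):
            present = [n for n, flag in zip(m.columns, mask) if flag]
            if present:
                regions["+".join(present)] = len(group)
        return regions

    def to_frame(self) -> pd.DataFrame:
        rows = [{"set": n, "size": self.sizes[n]} for n in self.names]
        for (a, b), size in self.pairwise.items():
            rows.append({"set": f"{a} & {b}", "size": size})
        if self.triple is not None:
            rows.append({"set": " & ".join(self.names), "size": self.triple})
        rows.append({"set": " | ".join(self.names), "size": self.union})
        return pd.DataFrame(rows)


def overlap_analysis(lists: dict[str, list[str]]) -> OverlapSummary:
    """Pairwise/triple intersections and union of 2–3 named gene lists.

    Duplicate ids within one list are de-duplicated with a logged
    warning; lists must already share an annotation version.
    """
    if not 2 <= len(lists) <= 3:
        raise ValueError("overlap_analysis takes two or three named lists")
    sets: dict[str, set[str]] = {}
    for name, genes in lists.items():
        if len(genes) != len(set(genes)):
            logger.warning(
                "list %r contains %d duplicate ids; de-duplicating",
                name,
                len(genes) - len(set(genes)),
            )
        sets[name] = set(genes)
    names = list(lists)
    universe = sorted(set().union(*sets.values()))
    membership = pd.DataFrame(
        {name: [g in sets[name] for g in universe] for name in names},
        index=pd.Index(universe, name="gene_id"),
    )
    pairwise = {
        (a, b): len(sets[a] & sets[b]) for a, b in combinations(names, 2)
    }
    triple = len(set.intersection(*sets.values())) if len(names) == 3 else None
    return OverlapSummary(
        names=names,
        sizes={n: len(sets[n]) for n in names},
        pairwise=pairwise,
        triple=triple,
        union=len(universe),
        membership=membership,
    )


def combine_evidence(
    screen_hits: list[str], transcriptomic_hits: list[str]
) -> pd.DataFrame:
    """Union of screen and transcriptomics gene lists with source flags.

    Returns one row per distinct gene with ``source`` in
    {"screen", "transcriptomics", "both"}; row count equals the union
    size and "both" flags exactly the intersection.
    """
    screen = set(screen_hits)
    transcriptomics = set(transcriptomic_hits)
    rows = []
    for gene in sorted(screen | transcriptomics):
        if gene in screen and gene in transcriptomics:
            source = "both"
        elif gene in screen:
            source = "screen"
        else:
            source = "transcriptomics"
        rows.append({"gene_id": gene, "source": source})
    return pd.DataFrame(rows, columns=["gene_id", "source"])


# ---------------------------------------------------------------------------
# IO


def read_gene_list(path: str | Path) -> list[str]:
    """One id per line (or first TSV column); whitespace trimmed."""
    with open(path) as fh:
        return [
            line.split("\t")[0].strip()
            for line in fh
            if line.strip() and not line.startswith("#")
        ]


def read_mapping_tsv(path: str | Path) -> pd.DataFrame:
    mapping = pd.read_csv(
        path, sep="\t", dtype=str, names=["source_id", "target_id"], header=0
    )
    mapping["source_id"] = mapping["source_id"].str.strip()
    mapping["target_id"] = mapping["target_id"].str.strip()
    return validate_mapping(mapping)


def write_mapping_tsv(mapping: pd.DataFrame, path: str | Path) -> None:
    validate_mapping(mapping)[["source_id", "target_id"]].to_csv(
        path, sep="\t", index=False
    )
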