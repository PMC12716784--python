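"""Synthetic study data with the statistical structure the pipeline assumes.

Emulates the inputs of the gland transcriptomics re-analysis and the
RNAi screen so every downstream stage is testable without external
downloads:

* transcript catalogs with variable lengths and multiple isoforms per
  gene;
* negative-binomially dispersed per-transcript read counts for the
  five-sample design (four gland tissues + anterior-abdomen control),
  with a planted subset of genes strongly enriched in all four gland
  tissues and natural zero counts for low-expression transcripts;
* many-to-one old->new gene-model mappings with a configurable number
  of pairwise fusions;
* screen phenotype tables over the seven morphology categories and the
  four gland volatiles.

Every generator is a pure function of its arguments including ``seed``:
identical calls give byte-identical outputs.  Per-sample random
sub-streams are derived deterministically from the seed and the sample
label, so adding a sample never perturbs the counts of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stinkgland.catalog import CATALOG_COLUMNS, validate_catalog
from stinkgland.design import CONTROL_TISSUE, GLAND_TISSUES, SampleDesign
from stinkgland.phenotype import (
    COMPOUND_CLASSES,
    COMPOUNDS,
    MORPHOLOGY_CATEGORIES,
    MORPHOLOGY_LABELS,
    REGIONS,
    STATUS_COLUMNS,
    WILD_TYPE,
)

TRUTH_COLUMNS = ["baseline_mean", "dispersion"] + [f"log2fc_{t}" for t in GLAND_TISSUES]

#: Reference library size at which ``baseline_mean`` is calibrated.
REFERENCE_LIBRARY_SIZE = 1_000_000
#: Reference transcript length (bp) at which ``baseline_mean`` is calibrated.
REFERENCE_LENGTH_BP = 1_000


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label RNG derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# catalogs


def generate_catalog(
    n_genes: int,
    isoforms_per_gene: int | tuple[int, int] = 1,
    length_range: tuple[int, int] = (300, 5000),
    seed: int = 0,
    annotation_version: str = "simOGS",
) -> pd.DataFrame:
    """Random transcript catalog.

    ``isoforms_per_gene`` is either a fixed count or an inclusive
    ``(low, high)`` range sampled uniformly per gene; transcript lengths
    are uniform over ``length_range`` (inclusive).
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    lo, hi = length_range
    if lo <= 0 or hi < lo:
        raise ValueError("length_range must be a positive, non-empty interval")
    if isinstance(isoforms_per_gene, int):
        iso_lo = iso_hi = isoforms_per_gene
    else:
        iso_lo, iso_hi = isoforms_per_gene
    if iso_lo < 1:
        raise ValueError("each gene needs at least one isoform")
    rng = _substream(seed, "catalog")
    rows = []
    for g in range(n_genes):
        gene_id = f"Tc_{g + 1:06d}"
        n_iso = int(rng.integers(iso_lo, iso_hi + 1))
        lengths = rng.integers(lo, hi + 1, size=n_iso)
        for k, length in enumerate(lengths, start=1):
            rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": f"{gene_id}.t{k}",
                    "length_bp": int(length),
                    "annotation_version": annotation_version,
                }
            )
    return validate_catalog(pd.DataFrame(rows, columns=CATALOG_COLUMNS))


# ---------------------------------------------------------------------------
# expression truth and counts


def make_truth(
    gene_ids: list[str],
    planted_genes: list[str] | None = None,
    effect_log2fc: float = 6.0,
    baseline_mean: float = 50.0,
    dispersion: float = 0.1,
    per_gene_baseline: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulation ground truth, one row per gene.

    Planted genes carry ``effect_log2fc`` in *all four* gland tissues
    (the signal the all-four fold-change rule detects); every other gene
    has log2fc 0 everywhere.  ``baseline_mean`` is the expected control
    count of a 1 kb transcript in a library of one million reads;
    ``dispersion`` is the negative-binomial alpha
    (variance = mu + alpha mu^2; 0 = Poisson).
    """
    planted = set(planted_genes or [])
    unknown = planted - set(gene_ids)
    if unknown:
        raise ValueError(f"planted gene {sorted(unknown)[0]!r} not in gene_ids")
    truth = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    if per_gene_baseline is not None:
        truth["baseline_mean"] = per_gene_baseline.reindex(gene_ids).to_numpy()
    else:
        truth["baseline_mean"] = baseline_mean
    truth["dispersion"] = dispersion
    for tissue in GLAND_TISSUES:
        truth[f"log2fc_{tissue}"] = [
            effect_log2fc if g in planted else 0.0 for g in gene_ids
        ]
    return truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial by gamma-Poisson mixture; Poisson at alpha=0."""
    if alpha == 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha)
    return rng.poisson(lam)


def simulate_counts(
    catalog: pd.DataFrame,
    design: SampleDesign,
    truth: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated mapped-read counts, transcripts x samples.

    The expected count of transcript *t* of gene *g* in sample *s* is

        baseline_mean(g) * 2^log2fc(g, tissue(s))
            * (library_size(s) / 1e6) * (length_bp(t) / 1000)

    i.e. the planted fold change acts multiplicatively on a length- and
    depth-proportional baseline; counts are then drawn independently per
    transcript from a negative binomial with that mean and the gene's
    dispersion.  Because draws are independent, the realized library
    total fluctuates around the nominal ``library_size``; the analysis
    only ever uses per-transcript counts, never library totals.
    """
    validate_catalog(catalog)
    missing = set(catalog["gene_id"]) - set(truth.index)
    if missing:
        raise KeyError(f"gene {sorted(missing)[0]!r} missing from simulation truth")
    genes = catalog["gene_id"].to_numpy()
    lengths = catalog["length_bp"].to_numpy(dtype=float)
    base = truth["baseline_mean"].reindex(genes).to_numpy(dtype=float)
    alphas = truth["dispersion"].reindex(genes).to_numpy(dtype=float)
    if (alphas < 0).any():
        raise ValueError("dispersion must be non-negative")
    counts = {}
    for sample in list(design.samples):
        tissue = design.samples[sample]
        if tissue == CONTROL_TISSUE:
            lfc = np.zeros(len(genes))
        else:
            lfc = truth[f"log2fc_{tissue}"].reindex(genes).to_numpy(dtype=float)
        mu = (
            base
            * np.exp2(lfc)
            * (design.library_size(sample) / REFERENCE_LIBRARY_SIZE)
            * (lengths / REFERENCE_LENGTH_BP)
        )
        rng = _substream(seed, f"counts/{sample}")
        if np.unique(alphas).size == 1:
            drawn = _nb_draw(rng, mu, float(alphas[0]))
        else:
            # per-gene dispersions: draw gamma heterogeneity first
            lam = np.where(
                alphas > 0,
                rng.gamma(np.where(alphas > 0, 1.0 / np.maximum(alphas, 1e-12), 1.0), mu * alphas),
                mu,
            )
            drawn = rng.poisson(lam)
        counts[sample] = drawn.astype(np.int64)
    return pd.DataFrame(
        counts, index=pd.Index(catalog["transcript_id"], name="transcript_id")
    )


# ---------------------------------------------------------------------------
# annotation mappings


def generate_geneset_mapping(
    new_catalog: pd.DataFrame,
    n_fusions: int = 0,
    seed: int = 0,
    old_version: str = "simOGS-old",
) -> pd.DataFrame:
    """Old->new gene-model mapping with pairwise fusions.

    Every new gene model receives one old model; ``n_fusions`` of them
    receive a second old model (two old models fused into one new one),
    so the mapping has ``n_genes + n_fusions`` old ids over ``n_genes``
    new ids.  Fusion partners are chosen uniformly at random.
    """
    new_genes = list(dict.fromkeys(new_catalog["gene_id"]))
    if n_fusions < 0 or n_fusions > max(len(new_genes) - 1, 0):
        raise ValueError("n_fusions must be between 0 and n_genes - 1")
    rng = _substream(seed, "mapping")
    fused = set(
        rng.choice(len(new_genes), size=n_fusions, replace=False).tolist()
        if n_fusions
        else []
    )
    rows = []
    old_serial = 0
    for i, new_id in enumerate(new_genes):
        copies = 2 if i in fused else 1
        for _ in range(copies):
            old_serial += 1
            rows.append(
                {"source_id": f"{old_version}_{old_serial:06d}", "target_id": new_id}
            )
    return pd.DataFrame(rows, columns=["source_id", "target_id"])


# ---------------------------------------------------------------------------
# screen tables


def default_reference_profile() -> pd.DataFrame:
    """Wild-type mean GC-MS peak areas per region (arbitrary units)."""
    return pd.DataFrame(
        {
            "MBQ": [100.0, 80.0],
            "EBQ": [120.0, 90.0],
            "1-C15": [60.0, 40.0],
            "1-C17": [50.0, 30.0],
        },
        index=pd.Index(REGIONS, name="region"),
    )


@dataclass(frozen=True)
class VolatileEffectModel:
    """How knock-down phenotypes perturb gland volatiles.

    For a gene with a morphological phenotype, each region x class cell
    is independently "reduced" with probability ``p_reduced[(region,
    class)]``; a reduced cell drops every compound of the class to
    ``reduced_scale`` times the reference area (well below the 10% call
    threshold), and both compounds of a class always move together —
    the coupling observed in the screen.  Wild-type-like genes keep the
    reference profile exactly.
    """

    p_reduced: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("abdominal", "benzoquinone"): 0.6,
            ("thoracic", "benzoquinone"): 0.6,
            ("abdominal", "alkene"): 0.3,
            ("thoracic", "alkene"): 0.3,
        }
    )
    reduced_scale: float = 0.02


#: Morphology category frequencies emulating the screen's phase-3
#: composition (dominated by less secretion, size-decreased glands and
#: darker secretion color, plus a small wild-type-like fraction).
DEFAULT_MORPHOLOGY_PROBS: dict[str, float] = {
    "I": 0.12,
    "II": 0.03,
    "III": 0.04,
    "IV": 0.44,
    "V": 0.04,
    "VI": 0.03,
    "VII": 0.25,
    WILD_TYPE: 0.05,
}


def simulate_screen_tables(
    gene_ids: list[str],
    morphology_probs: dict[str, float] | None = None,
    volatile_effect_model: VolatileEffectModel | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype records and GC-MS volatile profiles for a screen.

    Returns ``(records, profiles)``: one phenotype row per gene
    (morphology + per-cell volatile status) and a long profile table
    with one row per gene x region carrying the four peak areas.
    """
    probs = dict(DEFAULT_MORPHOLOGY_PROBS if morphology_probs is None else morphology_probs)
    unknown = set(probs) - set(MORPHOLOGY_LABELS)
    if unknown:
        raise ValueError(f"unknown morphology label {sorted(unknown)[0]!r}")
    total = sum(probs.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"morphology probabilities sum to {total}, expected 1")
    model = volatile_effect_model or VolatileEffectModel()
    reference = default_reference_profile()

    rng_morph = _substream(seed, "screen/morphology")
    labels = list(probs)
    weights = np.asarray([probs[l] for l in labels], dtype=float)
    weights = weights / weights.sum()  # guard fp drift after validation
    drawn = rng_morph.choice(len(labels), size=len(gene_ids), p=weights)

    rng_vol = _substream(seed, "screen/volatiles")
    records = []
    profile_rows = []
    for gene, li in zip(gene_ids, drawn):
        morphology = labels[li]
        row: dict[str, object] = {"gene_id": gene, "morphology": morphology}
        areas = reference.copy()
        for region in REGIONS:
            for cls, compounds in COMPOUND_CLASSES.items():
                p = model.p_reduced.get((region, cls), 0.0)
                # one uniform per cell keeps the stream aligned across genes
                u = rng_vol.random()
                reduced = morphology != WILD_TYPE and u < p
                row[f"{region}_{cls}"] = "reduced" if reduced else "normal"
                if reduced:
                    for compound in compounds:
                        areas.loc[region, compound] = (
                            model.reduced_scale * reference.loc[region, compound]
                        )
        records.append(row)
        for region in REGIONS:
            profile_rows.append(
                {"gene_id": gene, "region": region}
                | {c: float(areas.loc[region, c]) for c in COMPOUNDS}
            )
    records_df = pd.DataFrame(
        records, columns=["gene_id", "morphology", *STATUS_COLUMNS]
    )
    profiles_df = pd.DataFrame(
        profile_rows, columns=["gene_id", "region", *COMPOUNDS]
    )
    return records_df, profiles_df


# ---------------------------------------------------------------------------
# composition-specified tables (for reproducing published summaries)


def phenotype_table_from_composition(
    morphology_counts: dict[str, int],
    volatile_counts: dict[str, int] | None = None,
    prefix: str = "synth",
) -> pd.DataFrame:
    """Synthetic phenotype table with an exact prescribed composition.

    Unlike :func:`simulate_screen_tables`, which draws categories at
    random, this builds a table whose category *counts* are exactly the
    given composition — the shape needed to reproduce published summary
    tables whose per-gene rows are not available.

    ``morphology_counts`` maps morphology labels to gene counts.
    ``volatile_counts`` maps volatile categories to gene counts with
    keys ``all_volatiles`` (all four cells reduced), ``bq_both_only``
    (both benzoquinone cells, alkenes normal), ``alkene_both`` (both
    alkene cells, benzoquinones normal), ``restricted`` (a single
    abdominal-benzoquinone cell reduced) and ``none``; their total must
    equal the morphology total.
    """
    genes = []
    for label, n in morphology_counts.items():
        if label not in MORPHOLOGY_LABELS:
            raise ValueError(f"unknown morphology label {label!r}")
        genes.extend(label for _ in range(n))
    n_genes = len(genes)
    vol = dict(volatile_counts or {"none": n_genes})
    if sum(vol.values()) != n_genes:
        raise ValueError("volatile composition must cover every gene exactly once")
    patterns = {
        "all_volatiles": {c: "reduced" for c in STATUS_COLUMNS},
        "bq_both_only": {
            c: ("reduced" if c.endswith("benzoquinone") else "normal")
            for c in STATUS_COLUMNS
        },
        "alkene_both": {
            c: ("reduced" if c.endswith("alkene") else "normal")
            for c in STATUS_COLUMNS
        },
        "restricted": {
            c: ("reduced" if c == "abdominal_benzoquinone" else "normal")
            for c in STATUS_COLUMNS
        },
        "none": {c: "normal" for c in STATUS_COLUMNS},
    }
    statuses = []
    for category, n in vol.items():
        if category not in patterns:
            raise ValueError(f"unknown volatile category {category!r}")
        statuses.extend(patterns[category] for _ in range(n))
    rows = [
        {"gene_id": f"{prefix}_{i + 1:05d}", "morphology": m, **s}
        for i, (m, s) in enumerate(zip(genes, statuses))
    ]
    return pd.DataFrame(rows, columns=["gene_id", "morphology", *STATUS_COLUMNS])


def gene_lists_from_venn(
    region_counts: dict[str, int], names: tuple[str, str, str], prefix: str = "Tc"
) -> dict[str, list[str]]:
    """Three named gene lists realizing exact exclusive Venn region sizes.

    ``region_counts`` keys are '+'-joined subsets of ``names`` (e.g.
    ``"A+B"``); synthetic gene ids are minted so that each exclusive
    region has exactly the requested size.  Used to reconstruct
    published overlap structures from their printed region counts.
    """
    lists: dict[str, list[str]] = {n: [] for n in names}
    serial = 0
    for region, n in region_counts.items():
        members = region.split("+")
        unknown = set(members) - set(names)
        if unknown:
            raise ValueError(f"region {region!r} references unknown list {unknown}")
        for _ in range(n):
            serial += 1
            gene = f"{prefix}_{serial:06d}"
            for name in members:
                lists[name].append(gene)
    return lists
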