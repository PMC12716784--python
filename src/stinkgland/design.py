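"""Sample design: which library is which tissue.

The study design is one RNA-seq library per tissue: four gland samples
(female abdominal, female prothoracic, male abdominal, male prothoracic)
and a single control library from the anterior abdomen of wild-type
beetles.  Fold changes are always gland-vs-control, so the design must
contain exactly one control sample; the number of gland samples is four
in the canonical design but replicated designs are allowed for power
studies (each replicate is treated as its own sample column).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Canonical gland tissue labels, in the stable column order used by all
#: fold-change and report tables.
GLAND_TISSUES: tuple[str, ...] = (
    "female-abdominal",
    "female-prothoracic",
    "male-abdominal",
    "male-prothoracic",
)

#: The control tissue (anterior abdomen, no gland).
CONTROL_TISSUE = "anterior-abdomen-control"

VALID_TISSUES = GLAND_TISSUES + (CONTROL_TISSUE,)


@dataclass(frozen=True)
class SampleDesign:
    """Maps sample labels to tissues and nominal library sizes.

    Parameters
    ----------
    samples
        Mapping ``sample label -> tissue``; tissues must come from
        :data:`VALID_TISSUES`.
    library_sizes
        Mapping ``sample label -> nominal library size`` (expected total
        read count used by the simulator; the realized total of a
        simulated library differs because counts are drawn
        per-transcript independently).
    """

    samples: dict[str, str]
    library_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, tissue in self.samples.items():
            if tissue not in VALID_TISSUES:
                raise ValueError(f"unknown tissue {tissue!r} for sample {label!r}")
        n_control = sum(t == CONTROL_TISSUE for t in self.samples.values())
        if n_control != 1:
            raise ValueError(
                f"design must have exactly one control sample, found {n_control}"
            )
        for label, size in self.library_sizes.items():
            if label not in self.samples:
                raise ValueError(f"library size given for unknown sample {label!r}")
            if size <= 0:
                raise ValueError(f"library size for {label!r} must be positive")

    @property
    def control_sample(self) -> str:
        return next(s for s, t in self.samples.items() if t == CONTROL_TISSUE)

    @property
    def gland_samples(self) -> list[str]:
        """Gland sample labels in stable tissue order (then label order)."""
        order = {t: i for i, t in enumerate(GLAND_TISSUES)}
        glands = [s for s, t in self.samples.items() if t != CONTROL_TISSUE]
        return sorted(glands, key=lambda s: (order[self.samples[s]], s))

    def library_size(self, sample: str, default: int = 1_000_000) -> int:
        return self.library_sizes.get(sample, default)

    @classmethod
    def canonical(cls, library_size: int = 1_000_000) -> "SampleDesign":
        """One sample per tissue, labels equal to tissue names."""
        return cls(
            samples={t: t for t in VALID_TISSUES},
            library_sizes={t: library_size for t in VALID_TISSUES},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample": s,
                "tissue": t,
                "library_size": self.library_size(s),
            }
            for s, t in self.samples.items()
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SampleDesign":
        return cls(
            samples=dict(zip(frame["sample"], frame["tissue"])),
            library_sizes=dict(zip(frame["sample"], frame["library_size"].astype(int))),
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "SampleDesign":
        return cls.from_frame(pd.read_csv(path, sep="\t"))
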