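"""Study design: seasonal forms, developmental stages, and sample layout.

The emulated experiment contrasts wet-season (WS) and dry-season (DS) wing
forms at four developmental timepoints — 60% wanderer (Wr60), 50% prepupa
(PP50), 15% pupa (P15) and 50% pupa (P50) — with four biological replicates
per form x stage. One library is excluded by default to mirror the removal
of an outlier replicate from all downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

FORMS: tuple[str, ...] = ("WS", "DS")
STAGES: tuple[str, ...] = ("Wr60", "PP50", "P15", "P50")

#: library excluded from all analysis by default (outlier replicate)
DEFAULT_DROPPED: tuple[str, ...] = ("DS_rep2_P15",)


def sample_id(form: str, replicate: int, stage: str) -> str:
    return f"{form}_rep{replicate}_{stage}"


@dataclass(frozen=True)
class Sample:
    id: str
    form: str
    stage: str
    replicate: int


@dataclass
class SampleDesign:
    """The full sample layout plus the ids excluded from analysis."""

    samples: list[Sample]
    dropped: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = [s.id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("sample ids must be unique")
        unknown = set(self.dropped) - set(ids)
        if unknown:
            raise ValueError(f"dropped ids not in design: {sorted(unknown)}")
        for s in self.samples:
            if s.form not in FORMS:
                raise ValueError(f"unknown form {s.form!r}")
            if s.stage not in STAGES:
                raise ValueError(f"unknown stage {s.stage!r}")

    @property
    def analyzed(self) -> list[Sample]:
        """Samples retained for analysis (dropped libraries removed)."""
        drop = set(self.dropped)
        return [s for s in self.samples if s.id not in drop]

    def ids(self, *, analyzed_only: bool = True) -> list[str]:
        pool = self.analyzed if analyzed_only else self.samples
        return [s.id for s in pool]


def default_design(
    n_replicates: int = 4, dropped: tuple[str, ...] = DEFAULT_DROPPED
) -> SampleDesign:
    """The 2 forms x 4 stages x 4 replicates layout (32 libraries)."""
    samples = [
        Sample(sample_id(form, rep, stage), form, stage, rep)
        for form in FORMS
        for stage in STAGES
        for rep in range(1, n_replicates + 1)
    ]
    return SampleDesign(samples=samples, dropped=dropped)
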