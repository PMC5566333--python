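"""Benchmarking study design: SIS dilution groups and the per-site acquisition schedule.

The benchmark spikes 30 stable isotope-labeled standard (SIS) peptides,
partitioned into five groups of six, into a constant cell-lysate background.
Each group starts at a different top amount (sample S5) and is serially
diluted threefold four times (S4 down to S1), so five samples cover a wide
combined concentration range. Every site acquires the five samples once per
day on three days, with sample S4 injected in technical triplicate, giving
7 injections per day and 21 per site.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "DilutionGroup",
    "StudyDesign",
    "RunPlan",
    "build_design",
    "concentration_of",
    "acquisition_schedule",
    "all_runs",
    "design_to_csv",
    "design_from_csv",
    "schedule_to_csv",
    "schedule_from_csv",
]

DEFAULT_STARTS = (1.0, 10.0, 100.0, 1_000.0, 10_000.0)
GROUP_LABELS = ("A", "B", "C", "D", "E")


class InvalidDesignError(ValueError):
    """Raised when design parameters cannot yield a valid dilution scheme."""


@dataclass(frozen=True)
class DilutionGroup:
    """One group of six SIS peptides sharing a serial dilution series.

    ``start_fmol`` is the on-column amount in the top sample (S5); lower
    samples follow by successive division by the design dilution factor.
    """

    group_id: str
    peptide_ids: tuple[str, ...]
    start_fmol: float

    def __post_init__(self) -> None:
        if self.start_fmol <= 0:
            raise InvalidDesignError(f"start amount must be positive, got {self.start_fmol}")
        if len(set(self.peptide_ids)) != len(self.peptide_ids):
            raise InvalidDesignError("duplicate peptide ids within a group")


@dataclass(frozen=True)
class RunPlan:
    """A single planned injection at one site."""

    run_id: str
    site_id: str
    day: int
    sample_id: str
    replicate_index: int
    acquisition_order: int


@dataclass(frozen=True)
class StudyDesign:
    """Complete multi-site dilution-series design."""

    groups: tuple[DilutionGroup, ...]
    dilution_factor: float = 3.0
    n_samples: int = 5
    sites: tuple[str, ...] = ()
    days: tuple[int, ...] = (1, 3, 5)
    # injections per sample per day; S4 is run in technical triplicate
    replicate_plan: dict[str, int] = field(default_factory=lambda: {"S4": 3})
    sample_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise InvalidDesignError("dilution factor must be positive")
        all_peps = [p for g in self.groups for p in g.peptide_ids]
        if len(set(all_peps)) != len(all_peps):
            raise InvalidDesignError("peptide ids must be unique across groups")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(f"S{k}" for k in range(1, self.n_samples + 1))

    def replicates(self, sample_id: str) -> int:
        return self.replicate_plan.get(sample_id, 1)

    def group(self, group_id: str) -> DilutionGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(f"unknown group {group_id!r}")

    def group_of_peptide(self, peptide_id: str) -> DilutionGroup:
        for g in self.groups:
            if peptide_id in g.peptide_ids:
                return g
        raise KeyError(f"unknown peptide {peptide_id!r}")

    @property
    def peptide_ids(self) -> tuple[str, ...]:
        return tuple(p for g in self.groups for p in g.peptide_ids)

    def concentrations(self) -> pd.DataFrame:
        """All nominal (group, sample) on-column amounts in fmol, tidy format."""
        rows = [
            {
                "group_id": g.group_id,
                "sample_id": s,
                "nominal_fmol": concentration_of(self, g.group_id, s),
            }
            for g in self.groups
            for s in self.sample_ids
        ]
        return pd.DataFrame(rows)

    def min_concentration(self) -> float:
        return float(self.concentrations()["nominal_fmol"].min())

    def max_concentration(self) -> float:
        return float(self.concentrations()["nominal_fmol"].max())


def build_design(
    n_sites: int = 11,
    starts: tuple[float, ...] = DEFAULT_STARTS,
    dilution_factor: float = 3.0,
    peptide_ids: tuple[str, ...] | None = None,
    days: tuple[int, ...] = (1, 3, 5),
) -> StudyDesign:
    """Construct the benchmarking design.

    Default start amounts span 1 fmol to 10 pmol in decade steps; with a
    threefold dilution factor and five samples the resulting global on-column
    range is ``min(starts)/81`` to ``max(starts)`` (0.012–10,000 fmol for the
    defaults).
    """
    if n_sites < 1:
        raise InvalidDesignError("need at least one site")
    if len(starts) != len(GROUP_LABELS):
        raise InvalidDesignError(f"expected {len(GROUP_LABELS)} start amounts, got {len(starts)}")
    if any(s <= 0 for s in starts):
        raise InvalidDesignError("start amounts must be positive")
    if dilution_factor <= 0:
        raise InvalidDesignError("dilution factor must be positive")

    if peptide_ids is None:
        peptide_ids = tuple(f"SIS_{lab}{i}" for lab in GROUP_LABELS for i in range(1, 7))
    if len(peptide_ids) != 30:
        raise InvalidDesignError("expected 30 SIS peptide ids")

    groups = tuple(
        DilutionGroup(
            group_id=lab,
            peptide_ids=tuple(peptide_ids[6 * gi : 6 * (gi + 1)]),
            start_fmol=float(starts[gi]),
        )
        for gi, lab in enumerate(GROUP_LABELS)
    )
    sites = tuple(f"site{i:02d}" for i in range(1, n_sites + 1))
    return StudyDesign(groups=groups, dilution_factor=float(dilution_factor), sites=sites, days=days)


def concentration_of(design: StudyDesign, group_id: str, sample_id: str) -> float:
    """Nominal on-column amount (fmol) of a group's peptides in one sample.

    Sample ``S{n_samples}`` carries the group start amount; each step down is
    one division by the dilution factor.
    """
    g = design.group(group_id)
    if sample_id not in design.sample_ids:
        raise KeyError(f"unknown sample {sample_id!r}")
    k = int(sample_id[1:])
    return g.start_fmol / design.dilution_factor ** (design.n_samples - k)


def acquisition_schedule(design: StudyDesign, site_id: str) -> list[RunPlan]:
    """The ordered list of planned injections for one site.

    Within a day, samples are injected in ascending order with the S4
    technical replicates consecutive (the deposited study defers the exact
    order to a supplementary table, so this is a convention, configurable via
    ``design.sample_order``).
    """
    if site_id not in design.sites:
        raise KeyError(f"unknown site {site_id!r}")
    order = design.sample_order or design.sample_ids
    plans: list[RunPlan] = []
    counter = 0
    for day in design.days:
        for sample_id in order:
            for rep in range(1, design.replicates(sample_id) + 1):
                counter += 1
                plans.append(
                    RunPlan(
                        run_id=f"{site_id}_d{day}_{sample_id}_r{rep}",
                        site_id=site_id,
                        day=day,
                        sample_id=sample_id,
                        replicate_index=rep,
                        acquisition_order=counter,
                    )
                )
    return plans


def all_runs(design: StudyDesign) -> list[RunPlan]:
    """Planned injections for every site, in site order then acquisition order."""
    return [p for site in design.sites for p in acquisition_schedule(design, site)]


def runs_frame(plans: list[RunPlan]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "run_id": p.run_id,
                "site_id": p.site_id,
                "day": p.day,
                "sample_id": p.sample_id,
                "replicate_index": p.replicate_index,
                "acquisition_order": p.acquisition_order,
            }
            for p in plans
        ]
    )


# ---------------------------------------------------------------------------
# CSV serialization (one header line, UTF-8, '.' decimal separator)

def design_to_csv(design: StudyDesign) -> str:
    rows = [
        {
            "group_id": g.group_id,
            "peptide_id": p,
            "start_fmol": g.start_fmol,
            "dilution_factor": design.dilution_factor,
            "n_samples": design.n_samples,
        }
        for g in design.groups
        for p in g.peptide_ids
    ]
    return pd.DataFrame(rows).to_csv(index=False)


def design_from_csv(text: str, sites: tuple[str, ...] = (), days: tuple[int, ...] = (1, 3, 5)) -> StudyDesign:
    df = pd.read_csv(io.StringIO(text))
    groups = []
    for gid, sub in df.groupby("group_id", sort=True):
        groups.append(
            DilutionGroup(
                group_id=str(gid),
                peptide_ids=tuple(sub["peptide_id"]),
                start_fmol=float(sub["start_fmol"].iloc[0]),
            )
        )
    return StudyDesign(
        groups=tuple(groups),
        dilution_factor=float(df["dilution_factor"].iloc[0]),
        n_samples=int(df["n_samples"].iloc[0]),
        sites=tuple(sites),
        days=days,
    )


def schedule_to_csv(plans: list[RunPlan]) -> str:
    return runs_frame(plans).to_csv(index=False)


def schedule_from_csv(text: str) -> list[RunPlan]:
    df = pd.read_csv(io.StringIO(text))
    return [
        RunPlan(
            run_id=str(r.run_id),
            site_id=str(r.site_id),
            day=int(r.day),
            sample_id=str(r.sample_id),
            replicate_index=int(r.replicate_index),
            acquisition_order=int(r.acquisition_order),
        )
        for r in df.itertuples()
    ]


def with_sites(design: StudyDesign, sites: tuple[str, ...]) -> StudyDesign:
    return replace(design, sites=tuple(sites))
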