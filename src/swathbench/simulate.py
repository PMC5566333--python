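"""Synthetic multi-site SWATH-MS study generator with known ground truth.

Emulates the benchmarking design at the level of scored peak-group tables:
a constant cell-lysate background proteome queried by a spectral library,
30 SIS peptides in five threefold dilution groups, site-specific response
offsets and peptide-by-site interaction effects, nested lognormal noise
(injection / day / site), soft signal saturation at high load, a per-site
detection floor, MS1 signals with ~10-fold worse interference than MS2, and
1:1 target-decoy peak groups.

Signal model for a peptide query carrying amount ``a`` (fmol-equivalent)::

    area = gain * (soft_sat(a) * exp(eps) + n_floor * exp(eta))
    soft_sat(a) = a / (1 + a / saturation_level)
    gain = site_response_offset * peptide_response * site_pep_effect * day_effect

``n_floor = detection_floor / sn_at_floor`` is the interference-equivalent
amount, chosen so the synthetic signal-to-noise ratio crosses ``sn_at_floor``
(default 20, the bioanalytical LLOQ criterion) exactly at the detection
floor. MS1 uses the same model with a floor ``ms1_interference_scale`` times
higher. The library also contains queries for proteins absent from the
sample; absent and below-floor queries emit noise-only peak groups with
probability ``p_noise``, providing the false-candidate pool against which
FDR control is exercised, while decoys are generated identically so the
decoy score distribution matches the target null exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import RunPlan, StudyDesign, all_runs, concentration_of, runs_frame

__all__ = [
    "BackgroundProteome",
    "SiteProfile",
    "StudyDataset",
    "generate_background",
    "generate_sis_response_factors",
    "make_site_profiles",
    "simulate_run",
    "simulate_study",
]

N_SUB_SCORES = 4
N_FRAGMENTS = 6
SUB_SCORE_COLS = [f"sub_score_{i}" for i in range(1, N_SUB_SCORES + 1)]
FRAG_COLS = [f"frag_area_{i}" for i in range(1, N_FRAGMENTS + 1)]
# relative loading of the discriminating shift onto each sub-score
_SUB_WEIGHTS = np.array([1.0, 0.7, 0.45, 0.25])


def _rng(master_seed: int, *tags: str) -> np.random.Generator:
    """Independent substream derived from the master seed and string tags."""
    keys = [zlib.crc32(t.encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, *keys]))


def _sigma(cv: float) -> float:
    """Lognormal sigma giving coefficient of variation ``cv`` (fraction)."""
    return float(np.sqrt(np.log1p(cv**2)))


@dataclass(frozen=True)
class BackgroundProteome:
    """Library of peptide queries over present and library-only proteins.

    ``proteins``: protein_id, log10_abundance, present (bool).
    ``queries``: one row per peptide query (peptide + charge) with its
    proteotypic protein, response factor, library retention time, and six
    relative fragment intensities summing to 1.
    """

    proteins: pd.DataFrame
    queries: pd.DataFrame

    @property
    def n_present(self) -> int:
        return int(self.proteins["present"].sum())


@dataclass(frozen=True)
class SiteProfile:
    """Instrument/chromatography characteristics of one acquisition site."""

    site_id: str
    response_offset: float = 1.0
    peptide_site_effect_sd: float = 0.30  # log-scale sd of peptide-by-site effects
    cv_intraday: float = 0.05  # injection-level CV (fraction)
    cv_interday: float = 0.07  # day-level CV component (fraction)
    detection_floor: float = 0.1  # fmol-equivalent amount where S/N = sn_at_floor
    saturation_level: float = 30000.0  # fmol-equivalent soft-saturation scale
    ms1_interference_scale: float = 10.0  # MS1 floor / MS2 floor
    drift_per_day: float = 0.0  # multiplicative log-drift per day index
    sn_at_floor: float = 20.0
    floor_jitter_sd: float = 0.25  # per-record lognormal jitter of the floor
    interference_sd: float = 0.5  # lognormal sd of the noise-floor term
    ms1_gain: float = 3.0  # MS1 precursor response relative to MS2

    def __post_init__(self) -> None:
        for name in ("response_offset", "saturation_level", "ms1_interference_scale", "sn_at_floor", "ms1_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.detection_floor < 0:
            raise ValueError("detection_floor must be non-negative")


@dataclass
class StudyDataset:
    """All simulated run tables plus the ground truth they were drawn from."""

    design: StudyDesign
    runs: pd.DataFrame
    peakgroups: pd.DataFrame
    sis: pd.DataFrame
    truth: pd.DataFrame
    profiles: dict[str, SiteProfile]
    sis_response_factors: dict[str, float] = field(default_factory=dict)


def generate_background(
    n_proteins: int,
    span_orders: float = 4.5,
    mean_peptides: float = 8.0,
    seed: int = 0,
    absent_fraction: float = 0.5,
    second_charge_prob: float = 0.15,
    abundance_min_log10: float = -1.5,
) -> BackgroundProteome:
    """Draw a background proteome plus library-only (absent) proteins.

    Present-protein log10 abundances are uniform over ``span_orders`` decades
    starting at ``abundance_min_log10`` (fmol-equivalent units). The library
    additionally carries ``absent_fraction * n_proteins`` proteins that are
    absent from the sample, mimicking a spectral library that is a superset
    of the detectable proteome. Peptides per protein are 1 + Poisson(mean-1);
    ~15% of peptides are queried at a second charge state.
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if span_orders <= 0:
        raise ValueError("span_orders must be positive")
    rng = _rng(seed, "background")
    n_absent = int(round(n_proteins * absent_fraction))
    n_total = n_proteins + n_absent

    log_abund = rng.uniform(abundance_min_log10, abundance_min_log10 + span_orders, n_proteins)
    proteins = pd.DataFrame(
        {
            "protein_id": [f"P{i:05d}" for i in range(n_total)],
            "log10_abundance": np.concatenate([log_abund, np.full(n_absent, -np.inf)]),
            "present": np.concatenate([np.ones(n_proteins, bool), np.zeros(n_absent, bool)]),
        }
    )

    n_pep = 1 + rng.poisson(max(mean_peptides - 1.0, 0.0), n_total)
    prot_idx = np.repeat(np.arange(n_total), n_pep)
    n_peptides = int(n_pep.sum())
    pep_ids = [f"PEP{i:06d}" for i in range(n_peptides)]
    two_charges = rng.random(n_peptides) < second_charge_prob

    rows_pep, rows_charge, rows_prot = [], [], []
    for i, (pid, pi) in enumerate(zip(pep_ids, prot_idx)):
        charges = (2, 3) if two_charges[i] else (2,)
        for z in charges:
            rows_pep.append(pid)
            rows_charge.append(z)
            rows_prot.append(pi)
    n_q = len(rows_pep)

    frag_rel = rng.dirichlet(np.ones(N_FRAGMENTS), n_q)
    frag_rel = -np.sort(-frag_rel, axis=1)  # most intense fragment first
    queries = pd.DataFrame(
        {
            "peptide_query_id": [f"{p}/{z}" for p, z in zip(rows_pep, rows_charge)],
            "peptide_id": rows_pep,
            "charge": rows_charge,
            "protein_id": proteins["protein_id"].to_numpy()[rows_prot],
            "response_factor": rng.lognormal(0.0, 0.8, n_q),
            "library_rt": rng.uniform(300.0, 5700.0, n_q),
        }
    )
    for j, c in enumerate(FRAG_COLS):
        queries[f"rel_{c}"] = frag_rel[:, j]
    queries["log10_abundance"] = proteins["log10_abundance"].to_numpy()[rows_prot]
    queries["present"] = proteins["present"].to_numpy()[rows_prot]
    return BackgroundProteome(proteins=proteins, queries=queries)


def generate_sis_response_factors(design: StudyDesign, seed: int = 0, spread_sd: float = 0.6) -> dict[str, float]:
    """Per-SIS-peptide MS response factors, ranked and dealt round-robin.

    Factors are drawn lognormally, sorted by response, and assigned one at a
    time across groups A..E so every group spans the response range
    (mirroring how the physical peptides were partitioned).
    """
    rng = _rng(seed, "sis")
    n = len(design.peptide_ids)
    factors = np.sort(rng.lognormal(0.0, spread_sd, n))[::-1]
    n_groups = len(design.groups)
    out: dict[str, float] = {}
    per_group_counter = [0] * n_groups
    for rank, f in enumerate(factors):
        gi = rank % n_groups
        g = design.groups[gi]
        out[g.peptide_ids[per_group_counter[gi]]] = float(f)
        per_group_counter[gi] += 1
    return out


def make_site_profiles(
    design: StudyDesign,
    seed: int = 0,
    offset_range: tuple[float, float] = (0.5, 2.0),
    **overrides,
) -> dict[str, SiteProfile]:
    """One profile per site with log-uniform response offsets in ``offset_range``."""
    rng = _rng(seed, "profiles")
    lo, hi = offset_range
    offsets = np.exp(rng.uniform(np.log(lo), np.log(hi), len(design.sites)))
    return {
        s: SiteProfile(site_id=s, response_offset=float(off), **overrides)
        for s, off in zip(design.sites, offsets)
    }


def _site_peptide_effects(profile: SiteProfile, ids: pd.Index | np.ndarray, seed: int, tag: str) -> np.ndarray:
    """Lognormal peptide-by-site effects, fixed across runs of one site."""
    rng = _rng(seed, "site_eff", profile.site_id, tag)
    return np.exp(rng.normal(0.0, profile.peptide_site_effect_sd, len(ids)))


def _day_effects(profile: SiteProfile, n: int, day: int, seed: int, tag: str) -> np.ndarray:
    """Per-peptide day effects (chromatographic day-to-day variation)."""
    rng = _rng(seed, "day_eff", profile.site_id, f"d{day}", tag)
    sig = _sigma(profile.cv_interday)
    eff = np.exp(rng.normal(0.0, sig, n)) if sig > 0 else np.ones(n)
    if profile.drift_per_day:
        eff = eff * np.exp(profile.drift_per_day * day)
    return eff


def _soft_sat(amount: np.ndarray | float, saturation_level: float) -> np.ndarray | float:
    return amount / (1.0 + amount / saturation_level)


def simulate_run(
    proteome: BackgroundProteome,
    design: StudyDesign,
    profile: SiteProfile,
    run: RunPlan,
    decoy_ratio: float = 1.0,
    seed: int = 0,
    p_noise: float = 0.5,
    sis_response_factors: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one injection: (peak-group table, SIS area table, ground truth).

    Target peak groups are emitted for every truly-above-floor query and,
    with probability ``p_noise``, for below-floor or absent queries (as
    noise-only candidates with null sub-scores). Decoy peak groups are drawn
    from the same null, one candidate decoy per library query, emitted with
    the same probability scaled by ``decoy_ratio``.
    """
    if decoy_ratio <= 0:
        raise ValueError("decoy_ratio must be positive")
    if sis_response_factors is None:
        sis_response_factors = generate_sis_response_factors(design, seed)

    q = proteome.queries
    n_q = len(q)
    rng = _rng(seed, "run", run.run_id)

    rf = q["response_factor"].to_numpy()
    site_eff = _site_peptide_effects(profile, q.index, seed, "bg")
    day_eff = _day_effects(profile, n_q, run.day, seed, "bg")
    gain = profile.response_offset * rf * site_eff * day_eff

    amount = np.where(q["present"].to_numpy(), 10.0 ** q["log10_abundance"].to_numpy(), 0.0)
    n_floor = profile.detection_floor / profile.sn_at_floor
    sig_intra = _sigma(profile.cv_intraday)

    floor_i = profile.detection_floor * np.exp(rng.normal(0.0, profile.floor_jitter_sd, n_q))
    present = amount >= floor_i if profile.detection_floor > 0 else amount > 0

    signal = _soft_sat(amount, profile.saturation_level) * np.exp(rng.normal(0.0, sig_intra, n_q))
    interference = n_floor * np.exp(rng.normal(0.0, profile.interference_sd, n_q))
    area = gain * (signal + interference)

    emit = present | (rng.random(n_q) < p_noise)
    # discriminating shift: grows with how far the signal sits above the floor
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where((amount > 0) & (floor_i > 0), amount / floor_i, np.nan)
        shift = np.where(present, np.clip(1.5 + 1.2 * np.log10(np.where(rel > 0, rel, 1.0)), 0.0, 6.0), 0.0)
    sub = rng.normal(0.0, 1.0, (n_q, N_SUB_SCORES)) + shift[:, None] * _SUB_WEIGHTS[None, :]

    idx = np.flatnonzero(emit)
    pg = pd.DataFrame(
        {
            "run_id": run.run_id,
            "peptide_query_id": q["peptide_query_id"].to_numpy()[idx],
            "protein_id": q["protein_id"].to_numpy()[idx],
            "decoy": False,
            "rt": q["library_rt"].to_numpy()[idx] + rng.normal(0.0, 5.0, len(idx)),
        }
    )
    for j, c in enumerate(SUB_SCORE_COLS):
        pg[c] = sub[idx, j]
    rel_frag = q[[f"rel_{c}" for c in FRAG_COLS]].to_numpy()[idx]
    frag = rel_frag * area[idx, None]
    for j, c in enumerate(FRAG_COLS):
        pg[c] = frag[:, j]
    ms1_floor_amt = n_floor * profile.ms1_interference_scale
    ms1_interf = ms1_floor_amt * np.exp(rng.normal(0.0, profile.interference_sd, len(idx)))
    pg["ms1_area"] = profile.ms1_gain * gain[idx] * (signal[idx] + ms1_interf)

    # decoys: one candidate per library query, null everywhere
    n_decoy_pool = int(round(n_q * decoy_ratio))
    d_emit = rng.random(n_decoy_pool) < p_noise
    didx = np.flatnonzero(d_emit) % n_q
    d_area = gain[didx] * n_floor * np.exp(rng.normal(0.0, profile.interference_sd, len(didx)))
    dg = pd.DataFrame(
        {
            "run_id": run.run_id,
            "peptide_query_id": "DECOY_" + pd.Series(q["peptide_query_id"].to_numpy()[didx]),
            "protein_id": "DECOY_" + pd.Series(q["protein_id"].to_numpy()[didx]),
            "decoy": True,
            "rt": rng.uniform(300.0, 5700.0, len(didx)),
        }
    )
    dsub = rng.normal(0.0, 1.0, (len(didx), N_SUB_SCORES))
    for j, c in enumerate(SUB_SCORE_COLS):
        dg[c] = dsub[:, j]
    d_frag = q[[f"rel_{c}" for c in FRAG_COLS]].to_numpy()[didx] * d_area[:, None]
    for j, c in enumerate(FRAG_COLS):
        dg[c] = d_frag[:, j]
    dg["ms1_area"] = profile.ms1_gain * gain[didx] * ms1_floor_amt * np.exp(
        rng.normal(0.0, profile.interference_sd, len(didx))
    )

    peakgroups = pd.concat([pg, dg], ignore_index=True)

    truth = pd.DataFrame(
        {
            "run_id": run.run_id,
            "peptide_query_id": q["peptide_query_id"].to_numpy()[idx],
            "protein_id": q["protein_id"].to_numpy()[idx],
            "present": present[idx],
            "protein_present": q["present"].to_numpy()[idx],
            "true_amount": amount[idx],
            "expected_area": gain[idx] * _soft_sat(amount[idx], profile.saturation_level),
        }
    )

    sis = _simulate_sis(design, profile, run, rng, seed, sis_response_factors)
    return peakgroups, sis, truth


def _simulate_sis(
    design: StudyDesign,
    profile: SiteProfile,
    run: RunPlan,
    rng: np.random.Generator,
    seed: int,
    sis_rf: dict[str, float],
) -> pd.DataFrame:
    """SIS peptide areas for one run at MS2 and MS1 level (XIC-style table)."""
    peptides = list(design.peptide_ids)
    n = len(peptides)
    groups = [design.group_of_peptide(p).group_id for p in peptides]
    nominal = np.array([concentration_of(design, g, run.sample_id) for g in groups])
    rf = np.array([sis_rf[p] for p in peptides])
    site_eff = _site_peptide_effects(profile, np.arange(n), seed, "sis")
    day_eff = _day_effects(profile, n, run.day, seed, "sis")
    gain = profile.response_offset * rf * site_eff * day_eff
    sig_intra = _sigma(profile.cv_intraday)

    frames = []
    for ms_level, floor_scale, lvl_gain in (
        ("MS2", 1.0, 1.0),
        ("MS1", profile.ms1_interference_scale, profile.ms1_gain),
    ):
        n_floor = profile.detection_floor / profile.sn_at_floor * floor_scale
        signal = _soft_sat(nominal, profile.saturation_level) * np.exp(rng.normal(0.0, sig_intra, n))
        interference = n_floor * np.exp(rng.normal(0.0, profile.interference_sd, n))
        area = lvl_gain * gain * (signal + interference)
        with np.errstate(divide="ignore"):
            sn = np.where(n_floor > 0, (signal + interference) / n_floor, np.inf)
        frames.append(
            pd.DataFrame(
                {
                    "run_id": run.run_id,
                    "site_id": run.site_id,
                    "day": run.day,
                    "sample_id": run.sample_id,
                    "replicate_index": run.replicate_index,
                    "peptide_id": peptides,
                    "group_id": groups,
                    "nominal_fmol": nominal,
                    "ms_level": ms_level,
                    "area": area,
                    "sn": sn,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_study(
    design: StudyDesign,
    site_profiles: dict[str, SiteProfile] | None = None,
    seed: int = 0,
    dropout: int = 0,
    proteome: BackgroundProteome | None = None,
    n_proteins: int = 500,
    decoy_ratio: float = 1.0,
    p_noise: float = 0.5,
    **background_kwargs,
) -> StudyDataset:
    """Simulate the full multi-site study.

    Every planned run (21 per site) is simulated from an independently seeded
    substream; ``dropout`` randomly chosen runs are removed afterwards
    (emulating excluded acquisitions). Calling twice with the same seed gives
    identical tables.
    """
    if site_profiles is None:
        site_profiles = make_site_profiles(design, seed)
    missing = set(design.sites) - set(site_profiles)
    if missing:
        raise ValueError(f"no profile for sites {sorted(missing)}")
    if proteome is None:
        proteome = generate_background(n_proteins, seed=seed, **background_kwargs)
    sis_rf = generate_sis_response_factors(design, seed)

    plans = all_runs(design)
    if dropout >= len(plans):
        raise ValueError("dropout must be smaller than the number of planned runs")
    if dropout:
        drop_rng = _rng(seed, "dropout")
        dropped = set(drop_rng.choice(len(plans), size=dropout, replace=False).tolist())
        plans = [p for i, p in enumerate(plans) if i not in dropped]

    pg_frames, sis_frames, truth_frames = [], [], []
    for plan in plans:
        pg, sis, truth = simulate_run(
            proteome,
            design,
            site_profiles[plan.site_id],
            plan,
            decoy_ratio=decoy_ratio,
            seed=seed,
            p_noise=p_noise,
            sis_response_factors=sis_rf,
        )
        pg_frames.append(pg)
        sis_frames.append(sis)
        truth_frames.append(truth)

    return StudyDataset(
        design=design,
        runs=runs_frame(plans),
        peakgroups=pd.concat(pg_frames, ignore_index=True),
        sis=pd.concat(sis_frames, ignore_index=True),
        truth=pd.concat(truth_frames, ignore_index=True),
        profiles=site_profiles,
        sis_response_factors=sis_rf,
    )


def quiet_profile(site_id: str, **overrides) -> SiteProfile:
    """A noise-free site profile (useful for analytic checks)."""
    defaults = dict(
        response_offset=1.0,
        peptide_site_effect_sd=0.0,
        cv_intraday=0.0,
        cv_interday=0.0,
        detection_floor=0.0,
        saturation_level=1e12,
        floor_jitter_sd=0.0,
        interference_sd=0.0,
    )
    defaults.update(overrides)
    return SiteProfile(site_id=site_id, **defaults)
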