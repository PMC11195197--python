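"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed, and
serializes its generating truth (planted element coordinates, binding
parameters, profile shapes) so downstream fits and scans can be checked
against known ground truth.

The peak generator emulates a CLIP peak set: i.i.d. background sequence
of a chosen base composition, with concrete element realizations
overwritten (not inserted) at controlled gaps so peak length stays
fixed; accidental background matches are permitted, as in real sequence.
Peak heights are lognormal, with a multiplicative effect on peaks
carrying a planted adjacent pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np

from fbekit.adjacency import REGIONS, PeakRecord
from fbekit.binding import (
    BindingParams,
    EMSACurve,
    TitrationSeries,
    one_site_heats,
    one_site_specific,
    standard_schedule,
)
from fbekit.motif import FBE_PATTERNS, RNA_BASES, SYMBOL_SETS, ConsensusPattern

#: Uniform background composition.
UNIFORM_COMPOSITION: dict[str, float] = {b: 0.25 for b in RNA_BASES}

#: U-rich preset emulating 3'UTR base composition.
UTR_COMPOSITION: dict[str, float] = {"A": 0.3, "U": 0.4, "C": 0.15, "G": 0.15}


def _check_composition(composition: Mapping[str, float]) -> np.ndarray:
    probs = np.array([composition.get(b, 0.0) for b in RNA_BASES], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"composition must be nonnegative and sum to 1, got {dict(composition)}"
        )
    return probs


def gen_background(
    length: int, composition: Mapping[str, float] | None = None, seed: int = 0
) -> str:
    """i.i.d. random RNA string of ``length`` from ``composition``."""
    if length < 0:
        raise ValueError("length must be >= 0")
    probs = _check_composition(composition or UNIFORM_COMPOSITION)
    rng = np.random.default_rng(seed)
    idx = rng.choice(4, size=length, p=probs)
    return "".join(RNA_BASES[i] for i in idx)


def realize_element(class_name: str, seed: int | np.random.Generator = 0) -> str:
    """Draw a concrete element: degenerate positions uniform over their sets."""
    if class_name not in FBE_PATTERNS:
        raise ValueError(f"unknown element class {class_name!r}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = []
    for sym in FBE_PATTERNS[class_name].symbols:
        allowed = sorted(SYMBOL_SETS[sym])
        out.append(allowed[rng.integers(len(allowed))])
    return "".join(out)


def plant_pair(
    background: str,
    elem_5p: str,
    elem_3p: str,
    gap: int,
    offset: int,
) -> tuple[str, tuple[int, int]]:
    """Overwrite two elements into a background at a controlled gap.

    Returns the modified sequence and the 0-based starts of the two
    elements; the scanned gap of these coordinates equals ``gap`` by
    construction.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    if offset < 0:
        raise ValueError("offset must be >= 0")
    start_3p = offset + len(elem_5p) + gap
    end = start_3p + len(elem_3p)
    if end > len(background):
        raise ValueError(
            f"planting needs {end} nt but background has {len(background)}"
        )
    seq = (
        background[:offset]
        + elem_5p
        + background[offset + len(elem_5p) : start_3p]
        + elem_3p
        + background[end:]
    )
    return seq, (offset, start_3p)


def expected_match_probability(
    pattern: ConsensusPattern, composition: Mapping[str, float] | None = None
) -> float:
    """Per-offset match probability of a pattern on i.i.d. background.

    Product over pattern positions of the composition mass of each
    symbol's allowed base set; the analytic oracle for the scanner's
    false-positive rate ((L - m + 1) * p expected matches per sequence).
    """
    comp = composition or UNIFORM_COMPOSITION
    _check_composition(comp)
    p = 1.0
    for sym in pattern.symbols:
        p *= sum(comp.get(b, 0.0) for b in SYMBOL_SETS[sym])
    return p


@dataclass(frozen=True)
class PlantPlan:
    """Per-peak planting plan: element classes, concrete forms, gap."""

    class_5p: str
    class_3p: str
    gap: int
    offset: Optional[int] = None  # random placement when None

    def __post_init__(self) -> None:
        if "FBE9" not in (self.class_5p, self.class_3p):
            raise ValueError("a planted pair must include a canonical FBE9")


@dataclass
class PeakSimSpec:
    """Study conditions for the synthetic peak set.

    Heights are lognormal: background-only peaks ~ exp(N(logmean, logsd));
    peaks with a planted adjacent pair get an ``adjacent_multiplier``
    fold increase in median height.  Defaults put the background mean
    height near the observed all-peak average (~740 FPKM with logsd 1)
    and a 4-fold adjacent effect, matching the observed contrast between
    adjacent-FBE peaks and all peaks.
    """

    n_peaks: int = 200
    peak_length: int = 80
    background_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(UNIFORM_COMPOSITION)
    )
    planted: Sequence[PlantPlan] = ()
    fpkm_logmean: float = math.log(736.0) - 0.5  # lognormal mean ~736 FPKM
    fpkm_logsd: float = 1.0
    adjacent_multiplier: float = 4.0
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "three_prime_utr": 0.90,
            "five_prime_utr": 0.04,
            "cds": 0.05,
            "other": 0.01,
        }
    )
    mut_logsd: float = 0.3
    mut_logmean_planted: float = math.log(0.5)

    def __post_init__(self) -> None:
        _check_composition(self.background_composition)
        if self.adjacent_multiplier < 1:
            raise ValueError("adjacent_multiplier must be >= 1")
        if len(self.planted) > self.n_peaks:
            raise ValueError("more planting plans than peaks")


def default_plans(
    n: int, gaps: Sequence[int] = tuple(range(1, 21)), seed: int = 0
) -> list[PlantPlan]:
    """n planting plans cycling through ``gaps``, second element class drawn
    uniformly from the four classes (the canonical element is always one
    member; both-canonical pairs are legitimate)."""
    rng = np.random.default_rng(seed)
    classes = list(FBE_PATTERNS)
    plans = []
    for i in range(n):
        other = classes[rng.integers(len(classes))]
        first_is_fbe9 = bool(rng.integers(2))
        c5, c3 = ("FBE9", other) if first_is_fbe9 else (other, "FBE9")
        plans.append(PlantPlan(c5, c3, gaps[i % len(gaps)]))
    return plans


@dataclass
class GroundTruth:
    """Generating truth serialized alongside every synthetic dataset."""

    kind: str
    params: dict = field(default_factory=dict)
    planted: dict = field(default_factory=dict)  # peak_id -> plant record

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "params": self.params, "planted": self.planted},
            indent=2,
            sort_keys=True,
        )


def gen_peakset(
    spec: PeakSimSpec, seed: int = 0
) -> tuple[list[PeakRecord], GroundTruth]:
    """Generate a synthetic peak set with known planted-pair ground truth."""
    rng = np.random.default_rng(seed)
    probs = _check_composition(spec.background_composition)
    region_names = list(spec.region_probs)
    region_p = np.array([spec.region_probs[r] for r in region_names], float)
    region_p = region_p / region_p.sum()
    for r in region_names:
        if r not in REGIONS:
            raise ValueError(f"unknown region {r!r}")

    peaks: list[PeakRecord] = []
    truth = GroundTruth(
        kind="peakset",
        params={
            "n_peaks": spec.n_peaks,
            "peak_length": spec.peak_length,
            "fpkm_logmean": spec.fpkm_logmean,
            "fpkm_logsd": spec.fpkm_logsd,
            "adjacent_multiplier": spec.adjacent_multiplier,
            "seed": seed,
        },
    )
    n_planted = len(spec.planted)
    for i in range(spec.n_peaks):
        peak_id = f"peak_{i:05d}"
        gene_id = f"gene_{i:05d}"
        idx = rng.choice(4, size=spec.peak_length, p=probs)
        seq = "".join(RNA_BASES[j] for j in idx)
        planted_rec = None
        is_planted = i < n_planted
        if is_planted:
            plan = spec.planted[i]
            e5 = realize_element(plan.class_5p, rng)
            e3 = realize_element(plan.class_3p, rng)
            needed = len(e5) + plan.gap + len(e3)
            max_offset = spec.peak_length - needed
            if max_offset < 0:
                raise ValueError(
                    f"peak length {spec.peak_length} too short for plan {plan}"
                )
            offset = (
                plan.offset
                if plan.offset is not None
                else int(rng.integers(max_offset + 1))
            )
            seq, (s5, s3) = plant_pair(seq, e5, e3, plan.gap, offset)
            planted_rec = {
                "class_5p": plan.class_5p,
                "class_3p": plan.class_3p,
                "start_5p": s5,
                "start_3p": s3,
                "gap": plan.gap,
                "element_5p": e5,
                "element_3p": e3,
            }
            truth.planted[peak_id] = planted_rec

        logmean = spec.fpkm_logmean + (
            math.log(spec.adjacent_multiplier) if is_planted else 0.0
        )
        height_wt = float(np.exp(rng.normal(logmean, spec.fpkm_logsd)))
        mut_mu = spec.mut_logmean_planted if is_planted else 0.0
        height_mut = float(height_wt * np.exp(rng.normal(mut_mu, spec.mut_logsd)))
        region = region_names[rng.choice(len(region_names), p=region_p)]
        peaks.append(
            PeakRecord(
                peak_id=peak_id,
                gene_id=gene_id,
                region=region,
                sequence=seq,
                height_wt=height_wt,
                height_mut=height_mut,
            )
        )
    return peaks, truth


def gen_itc(
    params: BindingParams,
    schedule: TitrationSeries | None = None,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> tuple[TitrationSeries, GroundTruth]:
    """Simulate an ITC titration: forward-model heats plus additive
    Gaussian noise with sigma = noise_frac * max|heat|."""
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    schedule = schedule or standard_schedule()
    heats = one_site_heats(params, schedule)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_frac * np.abs(heats).max(), heats.shape)
    series = TitrationSeries(
        schedule.cell_volume,
        schedule.cell_conc0,
        schedule.syringe_conc,
        schedule.injection_volumes,
        tuple(float(h) for h in heats),
    )
    truth = GroundTruth(
        kind="itc",
        params={
            "n_sites": params.n_sites,
            "kd": params.kd,
            "delta_h": params.delta_h,
            "noise_frac": noise_frac,
            "seed": seed,
        },
    )
    return series, truth


def dilution_series(
    top: float = 5e-6, n_points: int = 12, factor: float = 2.0
) -> tuple[float, ...]:
    """Two-fold (by default) protein dilution series, ascending, molar."""
    return tuple(top / factor**i for i in reversed(range(n_points)))


def gen_emsa(
    bmax: float,
    kd: float,
    protein_concs: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    rna_conc: float = 5e-9,
) -> tuple[EMSACurve, GroundTruth]:
    """Simulate an EMSA binding curve (fraction bound vs protein conc)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    concs = tuple(protein_concs) if protein_concs is not None else dilution_series()
    frac = one_site_specific(bmax, kd, np.array(concs))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frac = np.clip(frac + rng.normal(0.0, noise_sd, frac.shape), 0.0, 1.0)
    curve = EMSACurve(concs, tuple(float(f) for f in frac), rna_conc)
    truth = GroundTruth(
        kind="emsa",
        params={"bmax": bmax, "kd": kd, "noise_sd": noise_sd, "seed": seed},
    )
    return curve, truth


def gen_fret(
    efficiency: float,
    total_intensity: float = 1000.0,
    n_measurements: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[float, float]], GroundTruth]:
    """Simulate FRET intensity pairs (I_564, I_668) at a true efficiency."""
    if not 0 <= efficiency <= 1:
        raise ValueError("efficiency must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_measurements):
        i668 = efficiency * total_intensity
        i564 = (1 - efficiency) * total_intensity
        if noise_sd > 0:
            i668 = max(i668 + rng.normal(0, noise_sd), 0.0)
            i564 = max(i564 + rng.normal(0, noise_sd), 0.0)
        rows.append((float(i564), float(i668)))
    truth = GroundTruth(
        kind="fret",
        params={
            "efficiency": efficiency,
            "total_intensity": total_intensity,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return rows, truth


@dataclass(frozen=True)
class ProfileShape:
    """Parametric germline expression shape along the distal-proximal axis.

    intensity(x) = distal_level * exp(-x / distal_decay)
                   + amplitude / (1 + exp(-(x - midpoint)/width))

    emulating the sigmoidal rise from low expression in the distal stem
    cell pool to a proximal plateau; ``distal_level`` raises the distal
    baseline and decays along the axis (a repression-defective mutant
    elevates the distal end while the proximal plateau stays put),
    units arbitrary.
    """

    amplitude: float = 100.0
    midpoint: float = 50.0
    width: float = 12.0
    distal_level: float = 5.0
    distal_decay: float = 25.0

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        return self.distal_level * np.exp(-x / self.distal_decay) + (
            self.amplitude / (1.0 + np.exp(-(x - self.midpoint) / self.width))
        )


def gen_profiles(
    shapes: Mapping[str, ProfileShape],
    n_gonads: int = 10,
    noise_sd: float = 5.0,
    positions: Sequence[float] | None = None,
    seed: int = 0,
):
    """Simulate per-gonad intensity profiles for each genotype.

    Additive Gaussian noise per position, clipped at zero (intensities
    are nonnegative).  Returns (profiles, ground truth).
    """
    from fbekit.profiles import IntensityProfile

    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    pos = np.asarray(
        positions if positions is not None else np.arange(0.0, 101.0, 1.0), float
    )
    rng = np.random.default_rng(seed)
    profiles = []
    for genotype, shape in shapes.items():
        base = shape.evaluate(pos)
        for g in range(n_gonads):
            vals = base
            if noise_sd > 0:
                vals = np.clip(base + rng.normal(0, noise_sd, pos.shape), 0, None)
            profiles.append(
                IntensityProfile(
                    gonad_id=f"{genotype}_{g:03d}",
                    genotype=genotype,
                    positions=tuple(float(p) for p in pos),
                    intensities=tuple(float(v) for v in vals),
                )
            )
    truth = GroundTruth(
        kind="profiles",
        params={
            "shapes": {k: asdict(v) for k, v in shapes.items()},
            "n_gonads": n_gonads,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )
    return profiles, truth
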