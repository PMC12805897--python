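"""Synthetic reporter time courses and colony sequence sets.

Emulates the two data types the pipeline consumes, so every stage is
testable without any external download:

* fluorescence/luminescence time courses drawn from the three-compartment
  expression model with cell-line presets (A549: mRNA half-life 400 min,
  fluorophore half-life 259 min; HEK293T: 350 / 179 min), a 60-min default
  maturation half-life for mKate2-class reporters, three technical
  replicates, and mean-one multiplicative log-normal measurement noise;
* colony tail-sequence sets containing a controlled fraction of shortened
  (adenine-deleted) and altered (spacer-substituted or spacer-deleted)
  clones for the instability analysis.

Sampling grids mirror the emulated assays: fluorescence imaging every
120 min from 300 to 4620 min (5-77 h), luminescence at 240/960/1440/2880/
4320 min (4/16/24/48/72 h).

Reproducibility: one experiment seed drives a named substream per
(variant, replicate) derived from a CRC32 of the variant label, so adding
variants never perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import TimeCourse
from .grammar import ADENINE, SPACER, Segment, TailDesign, render_sequence
from .kinetics import KineticParams, rate_from_half_life, simulate_closed_form
from .stability import ALTERED, INTACT, SHORTENED

__all__ = [
    "CellLinePreset",
    "VariantSpec",
    "SimulationDesign",
    "SimulatedClone",
    "FLUORESCENCE_GRID",
    "LUMINESCENCE_GRID",
    "make_preset",
    "default_variant_panel",
    "simulate_experiment",
    "simulate_colonies",
]

#: Imaging every 2 h from 5 h to 77 h post-transfection (minutes).
FLUORESCENCE_GRID = np.arange(300.0, 4621.0, 120.0)
#: Plate-reader luminescence at 4, 16, 24, 48 and 72 h (minutes).
LUMINESCENCE_GRID = np.array([240.0, 960.0, 1440.0, 2880.0, 4320.0])

#: Maturation half-life default (min) for mKate2-class reporters.  The fits
#: estimate this rate but no reference value is printed anywhere; 60 min is a
#: generator convenience in the range typical for red fluorescent proteins.
DEFAULT_K_MAT_HALF_LIFE = 60.0
DEFAULT_NOISE_CV = 0.05


@dataclass(frozen=True)
class CellLinePreset:
    """Cell-line-specific kinetics and sampling scheme for the generator."""

    name: str
    rna_half_life: float  # min
    protein_half_life: float  # min
    k_mat: float  # 1/min
    noise_cv: float = DEFAULT_NOISE_CV
    time_grid: np.ndarray = field(default_factory=lambda: FLUORESCENCE_GRID.copy())

    def __post_init__(self) -> None:
        if self.rna_half_life <= 0 or self.protein_half_life <= 0:
            raise ValueError("half-lives must be strictly positive")
        if self.k_mat <= 0:
            raise ValueError("k_mat must be strictly positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        grid = np.asarray(self.time_grid, dtype=float)
        if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
            raise ValueError("time_grid must be 1-D and strictly increasing")
        object.__setattr__(self, "time_grid", grid)


_PRESETS = {
    "A549": {"rna_half_life": 400.0, "protein_half_life": 259.0},
    "HEK293T": {"rna_half_life": 350.0, "protein_half_life": 179.0},
}


def make_preset(name: str, **overrides) -> CellLinePreset:
    """Build a named cell-line preset, or a custom one via keyword overrides."""
    key = name.upper()
    if key in _PRESETS:
        params = dict(_PRESETS[key])
    elif overrides:
        params = {}
    else:
        raise ValueError(
            f"unknown preset {name!r} (choose A549/HEK293T) and no custom "
            "parameters supplied"
        )
    params.setdefault("k_mat", rate_from_half_life(DEFAULT_K_MAT_HALF_LIFE))
    params.setdefault("noise_cv", DEFAULT_NOISE_CV)
    params.update(overrides)
    return CellLinePreset(name=name, **params)


@dataclass(frozen=True)
class VariantSpec:
    """One mRNA variant: a half-life multiplier and a translation rate."""

    label: str
    rna_half_life_multiplier: float = 1.0
    k_trans: float = 1.0

    def __post_init__(self) -> None:
        if self.rna_half_life_multiplier <= 0 or self.k_trans <= 0:
            raise ValueError("multiplier and k_trans must be strictly positive")


def default_variant_panel(n: int = 10) -> tuple[VariantSpec, ...]:
    """A panel of n variants spanning realistic between-variant variation.

    mRNA half-life multipliers are log-symmetric in [1/1.4, 1.4] (median ~1;
    the emulated study found little stability variation across tail designs)
    and translation rates span the observed up-to-six-fold output range.
    """
    if n < 1:
        raise ValueError("panel size must be >= 1")
    if n == 1:
        mults, k_trans = np.array([1.0]), np.array([2.0])
    else:
        mults = np.geomspace(1.0 / 1.4, 1.4, n)
        k_trans = np.geomspace(1.0, 6.0, n)
    return tuple(
        VariantSpec(f"v{i + 1:02d}", float(m), float(k))
        for i, (m, k) in enumerate(zip(mults, k_trans))
    )


@dataclass(frozen=True)
class SimulationDesign:
    """A full simulated experiment: preset x variant panel x replicates."""

    cell_line: CellLinePreset
    variants: tuple[VariantSpec, ...]
    n_replicates: int = 3
    seed: int = 0
    noise_model: str = "lognormal"  # or "additive"
    replicate_efficiency_cv: float = 0.0  # optional per-well efficiency factor

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_model not in ("lognormal", "additive"):
            raise ValueError("noise_model must be 'lognormal' or 'additive'")
        labels = [v.label for v in self.variants]
        if len(labels) != len(set(labels)):
            raise ValueError("variant labels must be unique")
        object.__setattr__(self, "variants", tuple(self.variants))


def _substream(seed: int, label: str, replicate: int) -> np.random.Generator:
    """Named substream: stable under adding/reordering variants."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode()), replicate])
    )


def simulate_experiment(design: SimulationDesign) -> list[TimeCourse]:
    """Simulate noisy fluorophore time courses for every variant x replicate."""
    preset = design.cell_line
    lambda_fluor = rate_from_half_life(preset.protein_half_life)
    courses = []
    cv = preset.noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv))) if cv > 0 else 0.0
    for variant in design.variants:
        params = KineticParams(
            lambda_rna=rate_from_half_life(
                preset.rna_half_life * variant.rna_half_life_multiplier
            ),
            k_trans=variant.k_trans,
            k_mat=preset.k_mat,
            lambda_fluor=lambda_fluor,
            m0=1.0,
        )
        clean = simulate_closed_form(params, preset.time_grid).fluor
        for rep in range(1, design.n_replicates + 1):
            rng = _substream(design.seed, variant.label, rep)
            signal = clean.copy()
            if design.replicate_efficiency_cv > 0:
                eff_sigma = float(
                    np.sqrt(np.log1p(design.replicate_efficiency_cv**2))
                )
                signal = signal * rng.lognormal(-0.5 * eff_sigma**2, eff_sigma)
            if cv > 0:
                if design.noise_model == "lognormal":
                    # mean-one multiplicative noise with the stated CV
                    factors = rng.lognormal(
                        -0.5 * sigma * sigma, sigma, size=signal.size
                    )
                    signal = signal * factors
                else:
                    signal = np.clip(
                        signal + rng.normal(0.0, cv * signal), 0.0, None
                    )
            courses.append(
                TimeCourse(
                    cell_line=preset.name,
                    variant=variant.label,
                    replicate=rep,
                    times=preset.time_grid,
                    signal=signal,
                )
            )
    return courses


@dataclass(frozen=True)
class SimulatedClone:
    """One simulated colony: sequence plus the generator's true class."""

    clone_id: str
    sequence: str
    true_class: str


def _shorten(design: TailDesign, rng: np.random.Generator) -> str:
    """Delete >= 1 adenines from one tract; redraw full deletions that would
    leave two spacers adjacent (their merge is ambiguous to classify)."""
    adenine_idx = [i for i, s in enumerate(design.segments) if s.kind == ADENINE]
    for _ in range(100):
        idx = int(rng.choice(adenine_idx))
        seg = design.segments[idx]
        n_del = int(rng.integers(1, seg.length + 1))
        if n_del == seg.length:
            left_spacer = idx > 0 and design.segments[idx - 1].kind == SPACER
            right_spacer = (
                idx < len(design.segments) - 1
                and design.segments[idx + 1].kind == SPACER
            )
            if left_spacer and right_spacer:
                continue  # redraw: would merge two spacers
        parts = []
        for i, s in enumerate(design.segments):
            if i == idx:
                parts.append("A" * (s.length - n_del))
            else:
                parts.append(s.sequence)
        result = "".join(parts)
        if not result:
            continue  # redraw: a single-tract design lost its whole tract
        return result
    raise RuntimeError(
        "could not draw an unambiguous adenine deletion for this design"
    )


def _alter(design: TailDesign, rng: np.random.Generator) -> str:
    """Substitute one spacer base or delete one whole spacer; for spacer-free
    references, substitute one tail adenine instead."""
    spacer_idx = [i for i, s in enumerate(design.segments) if s.kind == SPACER]
    if not spacer_idx:
        seq = list(render_sequence(design, "DNA", "sense"))
        pos = int(rng.integers(0, len(seq)))
        seq[pos] = str(rng.choice([b for b in "CGT" if b != seq[pos]]))
        return "".join(seq)
    idx = int(rng.choice(spacer_idx))
    mode = "substitute" if rng.random() < 0.5 else "delete"
    parts = []
    for i, seg in enumerate(design.segments):
        if i != idx:
            parts.append(seg.sequence)
            continue
        if mode == "delete":
            continue
        spacer = list(seg.sequence)
        pos = int(rng.integers(0, len(spacer)))
        spacer[pos] = str(rng.choice([b for b in "ACGT" if b != spacer[pos]]))
        parts.append("".join(spacer))
    return "".join(parts)


def simulate_colonies(
    reference: TailDesign,
    n: int,
    p_shorten: float,
    p_alter: float,
    seed: int = 0,
) -> list[SimulatedClone]:
    """Simulate a set of n sequenced colonies with controlled instability."""
    if n < 1:
        raise ValueError("need at least one colony")
    if p_shorten < 0 or p_alter < 0 or p_shorten + p_alter > 1:
        raise ValueError("need p_shorten, p_alter >= 0 and p_shorten + p_alter <= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    intact_seq = render_sequence(reference, "DNA", "sense")
    clones = []
    for i in range(1, n + 1):
        u = rng.random()
        if u < p_shorten:
            true_class, seq = SHORTENED, _shorten(reference, rng)
        elif u < p_shorten + p_alter:
            true_class, seq = ALTERED, _alter(reference, rng)
        else:
            true_class, seq = INTACT, intact_seq
        clones.append(SimulatedClone(f"clone_{i:03d}", seq, true_class))
    return clones
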