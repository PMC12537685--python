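"""Synthetic data generators for every stage of the CNV-editing pipeline.

Each generator emulates the statistical structure the corresponding
analysis assumes, at desk scale and under a fixed seed:

* T0 regeneration: every one of the 2n allele slots is edited
  independently with probability ``p_edit`` (high for a native
  single-guide RNA, lowered for the attenuated C30 + sgRNA regime where
  30 cytosines on the guide's 5' end throttle Cas9), with indel sizes
  drawn from a configurable spectrum.
* Clone sequencing: multinomial draws of plasmid clones over the allele
  proportions ``k_i / 2c`` of a true copy-number hypothesis.
* Droplet partitioning: positives ~ Binomial(T, 1 - exp(-lambda)) per
  channel — the exact sampling model behind the Poisson-law estimator.
* Selfing: i.i.d. 1:2:1 segregation of intact homolog blocks.
* Cas3 deletions: unidirectional intervals growing from the crRNA site
  toward the PAM side, truncated-exponential lengths.  This length law
  is a testing device, not a biological claim.

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .breeding import T0Genotype, selfing_distribution
from .ddpcr import DropletCount, WellMeasurement
from .inference import AlleleClass, AlleleCountTable

__all__ = [
    "SimConfig",
    "SimulatedLine",
    "gen_t0_population",
    "gen_clone_counts",
    "gen_droplets",
    "gen_selfing",
    "gen_cas3_deletions",
]

#: Indel-size spectrum used when none is supplied.  A stand-in shaped like
#: typical Cas9 outcomes (small deletions dominate); it only exercises
#: classification code paths and carries no biological weight.
DEFAULT_INDEL_SPECTRUM: dict[int, float] = {-1: 0.4, 1: 0.3, -3: 0.15, -2: 0.1, 2: 0.05}


@dataclass(frozen=True)
class SimConfig:
    """Shared knobs for the generators.

    ``p_edit`` defaults to 0.632, the attenuated-guide regime calibrated
    so a single-copy locus is bi-allelically edited in ~40% of lines
    (0.632² ≈ 0.4); a native guide corresponds to ~0.837 (0.837² ≈ 0.7).
    ``n_clones`` defaults to a 117-clone sequencing batch and
    ``n_droplets`` to a 15,000-droplet well.
    """

    seed: int = 0
    n: int = 3
    p_edit: float = 0.632
    indel_spectrum: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_SPECTRUM)
    )
    n_lines: int = 46
    n_droplets: int = 15_000
    reference_lambda: float = 0.5
    n_clones: int = 117

    def __post_init__(self) -> None:
        if not 0 <= self.p_edit <= 1:
            raise ValueError("p_edit must be in [0, 1]")
        total = sum(self.indel_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"indel spectrum sums to {total}, not 1")
        if 0 in self.indel_spectrum:
            raise ValueError("indel spectrum must not contain size 0 (wild type)")
        for name in ("n", "n_lines", "n_droplets", "n_clones"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SimulatedLine:
    """One regenerated T0 plant: allele states per slot plus its genotype.

    ``allele_states`` holds None for a functional (unedited) allele and
    the signed indel size otherwise; slots [0, n) sit on homolog 1 and
    [n, 2n) on homolog 2.
    """

    line_id: str
    genotype: T0Genotype
    allele_states: tuple[int | None, ...]

    @property
    def functional_alleles(self) -> int:
        return sum(s is None for s in self.allele_states)


def _rng(seed_or_rng: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def gen_t0_population(cfg: SimConfig) -> list[SimulatedLine]:
    """Simulate a T0 regeneration batch under per-allele independent editing."""
    rng = _rng(cfg.seed)
    sizes = np.array(sorted(cfg.indel_spectrum), dtype=int)
    probs = np.array([cfg.indel_spectrum[s] for s in sizes], dtype=float)
    n = cfg.n
    lines = []
    for i in range(cfg.n_lines):
        edited = rng.random(2 * n) < cfg.p_edit
        indels = rng.choice(sizes, size=2 * n, p=probs)
        states = tuple(int(indels[j]) if edited[j] else None for j in range(2 * n))
        a = sum(states[j] is None for j in range(n))
        b = sum(states[j] is None for j in range(n, 2 * n))
        lines.append(
            SimulatedLine(
                line_id=f"T0-{i:03d}", genotype=T0Genotype(a, b), allele_states=states
            )
        )
    return lines


def gen_clone_counts(
    true_c: int,
    allocation: Sequence[int],
    n_clones: int,
    seed: int | np.random.Generator,
) -> AlleleCountTable:
    """Multinomial clone-sequencing counts from a true allele allocation.

    ``allocation`` gives the number of allele slots per class and must sum
    to 2 * true_c; clones sample classes with probability k_i / (2c).
    """
    allocation = tuple(int(k) for k in allocation)
    if sum(allocation) != 2 * true_c:
        raise ValueError(f"allocation {allocation} must sum to {2 * true_c}")
    if any(k < 1 for k in allocation):
        raise ValueError("every class must occupy at least one allele slot")
    rng = _rng(seed)
    probs = np.asarray(allocation, dtype=float) / (2 * true_c)
    counts = rng.multinomial(n_clones, probs)
    classes = tuple(
        AlleleClass(label=f"allele_{i}") for i in range(len(allocation))
    )
    return AlleleCountTable(classes=classes, counts=tuple(int(c) for c in counts))


def gen_droplets(
    true_relative_value: float,
    calibrator_copies: int,
    cfg: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> tuple[WellMeasurement, WellMeasurement]:
    """Simulate one sample well and one calibrator well.

    The per-copy concentration scale is ``cfg.reference_lambda``; the
    calibrator's target channel runs at ``calibrator_copies`` times that
    scale divided by its own copy count — i.e. the calibrator defines
    relative value 1 — and the sample's target channel at
    ``true_relative_value`` times the calibrator's.  Droplet positives
    are Binomial(T, 1 - exp(-lambda)) in each channel.
    """
    if true_relative_value < 0:
        raise ValueError("true_relative_value must be non-negative")
    rng = _rng(cfg.seed if seed is None else seed)
    lam_ref = cfg.reference_lambda
    if not 0 < lam_ref < 5:
        raise ValueError("reference_lambda must be in (0, 5)")
    lam_cal_target = lam_ref  # calibrator ratio target/reference = 1 by definition
    lam_sample_target = true_relative_value * lam_ref
    if lam_sample_target >= 5:
        raise ValueError("sample target lambda out of the valid (0, 5) range")

    def draw(lam: float, channel: str) -> DropletCount:
        p = -np.expm1(-lam)
        pos = int(rng.binomial(cfg.n_droplets, p))
        return DropletCount(positives=pos, total=cfg.n_droplets, channel=channel)

    sample = WellMeasurement(
        sample_id="sample",
        target=draw(lam_sample_target, "target"),
        reference=draw(lam_ref, "reference"),
    )
    calibrator = WellMeasurement(
        sample_id="calibrator",
        target=draw(lam_cal_target, "target"),
        reference=draw(lam_ref, "reference"),
    )
    return sample, calibrator


def gen_selfing(
    parent: T0Genotype, n_progeny: int, seed: int | np.random.Generator
) -> list[T0Genotype]:
    """Draw selfed progeny genotypes i.i.d. from the 1:2:1 segregation law."""
    rng = _rng(seed)
    dist = selfing_distribution(parent)
    genotypes = list(dist)
    probs = np.array([float(dist[g]) for g in genotypes])
    idx = rng.choice(len(genotypes), size=n_progeny, p=probs)
    return [genotypes[i] for i in idx]


def gen_cas3_deletions(
    block_start: int,
    block_end: int,
    crrna_position: int,
    direction: Literal["left", "right"],
    n_lines: int,
    seed: int | np.random.Generator,
    mean_size: float = 4_000.0,
    max_size: float = 12_000.0,
    p_homozygous: float = 0.3,
) -> list[dict]:
    """Simulate unidirectional Cas3 deletion intervals per line.

    Deletions start at the crRNA site and extend toward ``direction``
    (the PAM side), with lengths from an exponential law censored at
    ``max_size`` (draws beyond the cap are clipped to it, so a mean far
    above the cap degenerates to the cap).  Each line is homozygously
    deleted with probability
    ``p_homozygous``, else heterozygously.  Returns one record per line:
    ``{"line_id", "interval": (start, end), "zygosity", "hits_target"}``
    where hits_target marks overlap with [block_start, block_end).
    """
    if not block_start < block_end:
        raise ValueError("empty target block")
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    rng = _rng(seed)
    records = []
    for i in range(n_lines):
        size = int(round(min(rng.exponential(mean_size), max_size)))
        if direction == "right":
            interval = (crrna_position, crrna_position + size)
        else:
            interval = (max(0, crrna_position - size), crrna_position)
        zygosity = "homozygous" if rng.random() < p_homozygous else "heterozygous"
        hits = interval[0] < block_end and interval[1] > block_start
        records.append(
            {
                "line_id": f"Cas3-{i:03d}",
                "interval": interval,
                "zygosity": zygosity,
                "hits_target": bool(hits),
            }
        )
    return records
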