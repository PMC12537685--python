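"""Droplet digital PCR copy-number quantification.

In ddPCR the reaction is partitioned into ~15,000-20,000 droplets; a
droplet is scored positive when it received at least one template
molecule.  With molecules Poisson-distributed over droplets, the mean
copies per droplet is recovered from the positive fraction p as

    lambda = -ln(1 - p),

with a delta-method standard error sqrt(p / (T (1 - p))) for T droplets.
The target-gene concentration is normalised by a single-copy reference
assay in the same well, and each sample's target/reference ratio is
expressed relative to a calibrator sample whose ratio defines copy
number 1.  Edited lines then fall on half-integer levels of the relative
value (each 0.5 step = one allele against a one-copy calibrator's 1.0),
which classifies them as unedited / heterozygous / homozygous deletions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

__all__ = [
    "DropletCount",
    "WellMeasurement",
    "ConcentrationEstimate",
    "RelativeCopyNumber",
    "LineClassification",
    "SaturatedWellError",
    "poisson_concentration",
    "relative_copy_number",
    "classify_line",
    "functional_allele_count",
    "pool_wells",
]

Channel = Literal["target", "reference"]
Category = Literal[
    "no_edit",
    "heterozygous_deletion",
    "homozygous_deletion",
    "double_homozygous_deletion",
    "ambiguous",
]


class SaturatedWellError(ValueError):
    """Every droplet positive: concentration is unbounded, dilute and re-run."""


@dataclass(frozen=True)
class DropletCount:
    positives: int
    total: int
    channel: Channel = "target"

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError("total droplets must be positive")
        if not 0 <= self.positives <= self.total:
            raise ValueError("positives must lie in [0, total]")


@dataclass(frozen=True)
class WellMeasurement:
    """Target and reference channel droplet counts from one well/sample."""

    sample_id: str
    target: DropletCount
    reference: DropletCount


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Mean copies per droplet with a 95% delta-method interval."""

    lam: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not 0 <= self.ci_low <= self.lam <= self.ci_high:
            raise ValueError("interval must bracket the estimate")


@dataclass(frozen=True)
class RelativeCopyNumber:
    sample_id: str
    value: float
    ci_low: float
    ci_high: float
    calibrator_id: str


@dataclass(frozen=True)
class LineClassification:
    sample_id: str
    category: Category
    nearest_level: float


def poisson_concentration(d: DropletCount, z: float = 1.96) -> ConcentrationEstimate:
    """Estimate copies per droplet from the positive-droplet fraction.

    lambda = -ln(1 - p); the interval is lambda ± z * sqrt(p / (T(1-p))).
    A fully positive well has no finite estimate and raises
    :class:`SaturatedWellError`.
    """
    if d.positives == d.total:
        raise SaturatedWellError(
            f"{d.positives}/{d.total} droplets positive: lambda unbounded"
        )
    p_hat = d.positives / d.total
    lam = -math.log1p(-p_hat)
    se = math.sqrt(p_hat / (d.total * (1.0 - p_hat)))
    return ConcentrationEstimate(
        lam=lam, ci_low=max(0.0, lam - z * se), ci_high=lam + z * se
    )


def _ratio_with_relvar(well: WellMeasurement, z: float) -> tuple[float, float]:
    """Target/reference concentration ratio and its squared relative error."""
    tgt = poisson_concentration(well.target, z)
    ref = poisson_concentration(well.reference, z)
    if ref.lam == 0:
        raise ValueError(f"reference channel of {well.sample_id} has no positives")
    ratio = tgt.lam / ref.lam
    relvar = 0.0
    for est, d in ((tgt, well.target), (ref, well.reference)):
        if est.lam > 0:
            p_hat = d.positives / d.total
            relvar += p_hat / (d.total * (1.0 - p_hat)) / est.lam**2
    return ratio, relvar


def relative_copy_number(
    sample: WellMeasurement, calibrator: WellMeasurement, z: float = 1.96
) -> RelativeCopyNumber:
    """Sample target/reference ratio normalised to the calibrator's ratio.

    The calibrator is the one-copy baseline, so its own relative value is
    exactly 1.  The interval propagates the four independent Poisson-law
    variances on the log scale; a sample with zero positive target
    droplets gets value 0 with a degenerate interval.
    """
    cal_ratio, cal_relvar = _ratio_with_relvar(calibrator, z)
    if cal_ratio == 0:
        raise ValueError(
            f"calibrator {calibrator.sample_id} has no positive target droplets"
        )
    if sample.target.positives == 0:
        return RelativeCopyNumber(
            sample_id=sample.sample_id,
            value=0.0,
            ci_low=0.0,
            ci_high=0.0,
            calibrator_id=calibrator.sample_id,
        )
    ratio, relvar = _ratio_with_relvar(sample, z)
    value = ratio / cal_ratio
    log_se = math.sqrt(relvar + cal_relvar)
    return RelativeCopyNumber(
        sample_id=sample.sample_id,
        value=value,
        ci_low=value * math.exp(-z * log_se),
        ci_high=value * math.exp(z * log_se),
        calibrator_id=calibrator.sample_id,
    )


def classify_line(
    r: RelativeCopyNumber,
    wildtype_relative_value: float,
    tolerance: float = 0.25,
) -> LineClassification:
    """Snap a relative copy number to the nearest half-integer allele level.

    Levels are multiples of 0.5 in [0, wildtype_relative_value].  Each
    0.5 step below wild type is one deleted allele: one step means a
    heterozygous deletion, two a homozygous one, and level 0 means every
    target copy on both homologs is gone.  Values farther than
    ``tolerance`` from every level are ambiguous rather than forced.
    """
    wt = wildtype_relative_value
    if wt <= 0 or round(wt * 2) != wt * 2:
        raise ValueError("wildtype_relative_value must be a positive multiple of 0.5")
    if r.value < 0:
        raise ValueError("relative copy number cannot be negative")
    levels = [k * 0.5 for k in range(int(round(wt * 2)) + 1)]
    nearest = min(levels, key=lambda lv: (abs(r.value - lv), lv))
    if abs(r.value - nearest) > tolerance:
        category: Category = "ambiguous"
    elif nearest == wt:
        category = "no_edit"
    elif nearest == 0.0:
        category = "double_homozygous_deletion"
    elif math.isclose(nearest, wt - 0.5):
        category = "heterozygous_deletion"
    elif math.isclose(nearest, wt - 1.0):
        category = "homozygous_deletion"
    else:
        category = "ambiguous"
    return LineClassification(
        sample_id=r.sample_id, category=category, nearest_level=nearest
    )


def functional_allele_count(
    r: RelativeCopyNumber, calibrator_alleles: int
) -> tuple[int, float]:
    """Integer functional-allele estimate given the calibrator's allele count.

    estimate = round(value * calibrator_alleles); the residual from the
    integer is returned for QC (large residuals flag noisy wells or a
    wrong calibrator assumption).
    """
    if calibrator_alleles < 1:
        raise ValueError("calibrator_alleles must be positive")
    raw = r.value * calibrator_alleles
    estimate = int(math.floor(raw + 0.5))
    return estimate, raw - estimate


def pool_wells(wells: Iterable[WellMeasurement], sample_id: str | None = None) -> WellMeasurement:
    """Merge replicate wells of one sample by summing droplet counts."""
    wells = list(wells)
    if not wells:
        raise ValueError("no wells to pool")
    ids = {w.sample_id for w in wells}
    if sample_id is None:
        if len(ids) > 1:
            raise ValueError(f"pooling across samples {sorted(ids)}; pass sample_id")
        sample_id = wells[0].sample_id
    return WellMeasurement(
        sample_id=sample_id,
        target=DropletCount(
            positives=sum(w.target.positives for w in wells),
            total=sum(w.target.total for w in wells),
            channel="target",
        ),
        reference=DropletCount(
            positives=sum(w.reference.positives for w in wells),
            total=sum(w.reference.total for w in wells),
            channel="reference",
        ),
    )
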