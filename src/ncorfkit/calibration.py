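"""Pass-threshold calibration from annotated-CDS score distributions.

A normal distribution is moment-fitted to each metric's scores over
annotated protein-coding CDSs.  The PIF and Uniformity thresholds are the
lower fitted-normal point exceeded by 95% of reference CDSs
(mu + z(tail) * sigma with tail = 0.05, i.e. mu - 1.645 sigma); the
Drop-off threshold is the fitted mean.  An ORF passes a dataset when all
three of its scores meet that dataset's thresholds (missing scores fail),
and enters the Primary set when it passes in at least one dataset.

The thresholds published for the two pooled human resources ship as named
defaults ("bodymap_v45", "ribocrypt_v45") so scoring can run without
calibration data.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .annotation_io import ValidationError
from .signatures import SignatureScores

__all__ = [
    "MetricFit",
    "ThresholdSet",
    "DEFAULT_THRESHOLDS",
    "fit_reference",
    "derive_thresholds",
    "passes",
    "select_primary",
    "thresholds_to_toml",
    "thresholds_from_toml",
]

METRICS = ("pif", "uniformity", "dropoff")


@dataclass(frozen=True)
class MetricFit:
    """Normal moment fit for one metric over reference CDS scores."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")


@dataclass
class ThresholdSet:
    """Per-dataset pass thresholds, with the fits behind them when calibrated."""

    dataset_id: str
    pif: float
    uniformity: float
    dropoff: float
    fits: dict[str, MetricFit] | None = None

    def __post_init__(self) -> None:
        for m in METRICS:
            v = getattr(self, m)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"threshold {m}={v} outside [0, 1]")


#: published thresholds for the two pooled test datasets
DEFAULT_THRESHOLDS = {
    "bodymap_v45": ThresholdSet("bodymap_v45", pif=0.7589, uniformity=0.713,
                                dropoff=0.92),
    "ribocrypt_v45": ThresholdSet("ribocrypt_v45", pif=0.5112,
                                  uniformity=0.8779, dropoff=0.88),
}


def fit_reference(scores: list[float]) -> MetricFit:
    """Moment fit: sample mean and unbiased sample sd of reference scores."""
    finite = [s for s in scores if s is not None and np.isfinite(s)]
    if len(finite) < 2:
        raise ValidationError("fit_reference needs at least 2 finite scores")
    arr = np.asarray(finite, dtype=float)
    return MetricFit(mu=float(arr.mean()), sigma=float(arr.std(ddof=1)))


def _clamp(x: float) -> float:
    return min(1.0, max(0.0, x))


def derive_thresholds(
    fits: dict[str, MetricFit], dataset_id: str, tail: float = 0.05
) -> ThresholdSet:
    """Thresholds from per-metric fits.

    PIF/Uniformity: the fitted-normal quantile below which only ``tail`` of
    reference CDSs fall (mu - 1.645 sigma at the default 5% tail).
    Drop-off: the fitted mean.  All clamped to [0, 1].
    """
    missing = [m for m in METRICS if m not in fits]
    if missing:
        raise ValidationError(f"derive_thresholds: missing fits for {missing}")
    z = float(norm.ppf(tail))
    return ThresholdSet(
        dataset_id=dataset_id,
        pif=_clamp(fits["pif"].mu + z * fits["pif"].sigma),
        uniformity=_clamp(fits["uniformity"].mu + z * fits["uniformity"].sigma),
        dropoff=_clamp(fits["dropoff"].mu),
        fits=dict(fits),
    )


def passes(scores: SignatureScores, thr: ThresholdSet) -> bool:
    """True iff all three scores are present and meet the thresholds (>=)."""
    if scores.dataset_id != thr.dataset_id:
        raise ValidationError(
            f"dataset mismatch: scores from {scores.dataset_id!r}, "
            f"thresholds for {thr.dataset_id!r}"
        )
    for m in METRICS:
        v = getattr(scores, m)
        if v is None or v < getattr(thr, m):
            return False
    return True


def select_primary(flags: list[bool]) -> bool:
    """Primary-set rule: pass in at least one evaluated dataset."""
    if not flags:
        raise ValidationError("select_primary: no datasets evaluated")
    return any(flags)


def thresholds_to_toml(thr: ThresholdSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(f'dataset_id = "{thr.dataset_id}"\n')
        for m in METRICS:
            fh.write(f"{m} = {getattr(thr, m)!r}\n")
        if thr.fits:
            for m, fit in thr.fits.items():
                fh.write(f"\n[fits.{m}]\nmu = {fit.mu!r}\nsigma = {fit.sigma!r}\n")


def thresholds_from_toml(path) -> ThresholdSet:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    fits = None
    if "fits" in data:
        fits = {m: MetricFit(**v) for m, v in data["fits"].items()}
    return ThresholdSet(
        dataset_id=data["dataset_id"],
        pif=data["pif"],
        uniformity=data["uniformity"],
        dropoff=data["dropoff"],
        fits=fits,
    )
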