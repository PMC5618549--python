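"""Model/Results front-end tying the pieces together.

:class:`JunctionSaturationModel` is built from a batch of samples (or a
pre-computed multiplicity spectrum) and, on :meth:`fit`, calibrates the
virtual-event correction and — when the raw samples are available —
evaluates the model against sub-batch resampling.  The returned
:class:`JunctionSaturationResults` carries prediction curves, the basal
observation rate, unique-event statistics and a printable summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .junction_io import SampleJunctions, read_spectrum_table
from .model import (
    DEFAULT_MU_V,
    PredictionCurve,
    calibrate_virtual_count,
    predict_curve,
    unique_underestimation_fraction,
)
from .spectrum import MultiplicitySpectrum, build_spectrum, ushape_fraction
from .subsample import (
    SmoothedCurve,
    SubsampleResult,
    UniqueEventStats,
    draw_subbatches,
    median_relative_deviation,
    smooth_curve,
    terminal_slope,
    unique_event_stats,
)

__all__ = ["JunctionSaturationModel", "JunctionSaturationResults"]


class JunctionSaturationModel:
    """Saturation model for gap-site detection in a batch of samples.

    Parameters
    ----------
    spectrum : MultiplicitySpectrum
        Multiplicity spectrum of the training batch (no virtual bins).
    samples : sequence of SampleJunctions, optional
        The underlying samples; required for the resampling-based
        evaluation (smoothed curve, basal rate, unique-event statistics).
    """

    def __init__(
        self,
        spectrum: MultiplicitySpectrum,
        samples: Optional[Sequence[SampleJunctions]] = None,
    ):
        if spectrum.virtual:
            raise ValueError("fit from a spectrum without virtual bins")
        self.spectrum = spectrum
        self.samples = list(samples) if samples is not None else None

    @classmethod
    def from_samples(cls, samples: Sequence[SampleJunctions]) -> "JunctionSaturationModel":
        return cls(build_spectrum(samples), samples=samples)

    @classmethod
    def from_spectrum_file(cls, path) -> "JunctionSaturationModel":
        return cls(read_spectrum_table(path).without_virtual())

    def fit(
        self,
        mu_v: float = DEFAULT_MU_V,
        n_reps: int = 200,
        size_range: Optional[tuple[int, int]] = None,
        span: float = 0.75,
        seed: int = 0,
    ) -> "JunctionSaturationResults":
        """Calibrate the correction and evaluate the model.

        ``mu_v`` is the fractional multiplicity given to virtual events;
        the virtual count is determined in closed form.  When samples are
        attached, ``n_reps`` sub-batches are drawn (sizes uniform on
        ``size_range``, default 2..n-1, seeded by ``seed``) and smoothed
        with loess span ``span``.
        """
        n = self.spectrum.n
        m_v = calibrate_virtual_count(self.spectrum, mu_v)
        grid = list(range(1, n + 1))
        raw = predict_curve(self.spectrum, grid, corrected=False)
        corrected = predict_curve(self.spectrum, grid, corrected=True, mu_v=mu_v)

        subsamples = smoothed = gbr = unique = raw_dev = corr_dev = None
        if self.samples is not None and n >= 2:
            subsamples = draw_subbatches(
                self.samples, n_reps=n_reps, size_range=size_range, seed=seed
            )
            smoothed = smooth_curve(subsamples, span=span)
            gbr = terminal_slope(smoothed)
            unique = unique_event_stats(self.samples, gbr=gbr)
            raw_dev = median_relative_deviation(raw, smoothed)
            corr_dev = median_relative_deviation(corrected, smoothed)

        return JunctionSaturationResults(
            model=self,
            mu_v=mu_v,
            m_v=m_v,
            raw_curve=raw,
            corrected_curve=corrected,
            subsamples=subsamples,
            smoothed=smoothed,
            gbr=gbr,
            unique=unique,
            raw_deviation_pct=raw_dev,
            corrected_deviation_pct=corr_dev,
        )


@dataclass
class JunctionSaturationResults:
    """Fitted saturation model: calibrated correction plus diagnostics."""

    model: JunctionSaturationModel
    mu_v: float
    m_v: float
    raw_curve: PredictionCurve
    corrected_curve: PredictionCurve
    subsamples: Optional[list[SubsampleResult]]
    smoothed: Optional[SmoothedCurve]
    gbr: Optional[float]
    unique: Optional[UniqueEventStats]
    raw_deviation_pct: Optional[float]
    corrected_deviation_pct: Optional[float]

    @property
    def spectrum(self) -> MultiplicitySpectrum:
        return self.model.spectrum

    def predict(self, nu_values: Sequence[int], corrected: bool = True) -> PredictionCurve:
        """Expected observed gap-sites at the given batch sizes."""
        return predict_curve(
            self.spectrum, nu_values, corrected=corrected, mu_v=self.mu_v
        )

    def curves_frame(self) -> pd.DataFrame:
        """Raw/corrected predictions (and smoothed observations) by size."""
        frame = pd.DataFrame(
            {
                "nu": self.raw_curve.nu,
                "raw": self.raw_curve.expected,
                "corrected": self.corrected_curve.expected,
            }
        )
        if self.smoothed is not None:
            obs = pd.DataFrame(
                {"nu": self.smoothed.nu, "smoothed": self.smoothed.mean_observed}
            )
            frame = frame.merge(obs, on="nu", how="left")
        return frame

    def summary(self) -> str:
        spec = self.spectrum
        n = spec.n
        total = spec.total_sites()
        lines = [
            "Junction saturation model",
            "=" * 58,
            f"batch size n                  {n}",
            f"distinct gap-sites |S_n|      {total}",
            f"unique (multiplicity 1)       {spec.z.get(1, 0)}",
        ]
        if n >= 5:
            low, high = 5, max(5, n - 4)
            label = f"U-shape: frac <{low} or >{high}"
            lines.append(f"{label:<30}{ushape_fraction(spec, low, high):.3f}")
        raw_end = self.raw_curve.expected[-1]
        lines += [
            "-" * 58,
            f"raw prediction at nu=n        {raw_end:.1f} "
            f"({100 * (1 - raw_end / total):.1f}% deficit)",
            f"unique-event bias (1-1/n)^n   "
            f"{unique_underestimation_fraction(n):.3f}",
            f"virtual events: mu_v          {self.mu_v:g}",
            f"                m_v           {self.m_v:.1f}",
            f"corrected prediction at nu=n  {self.corrected_curve.expected[-1]:.1f}",
        ]
        if self.smoothed is not None:
            lines += [
                "-" * 58,
                f"sub-batches drawn             {len(self.subsamples)}",
                f"median deviation, raw         {self.raw_deviation_pct:.2f}%",
                f"median deviation, corrected   {self.corrected_deviation_pct:.2f}%",
                f"basal rate gbr                {self.gbr:.1f} sites/sample",
                f"unique sites total            {self.unique.total_unique}",
                f"unique per sample (mean, SD)  {self.unique.per_sample_mean:.1f}, "
                f"{self.unique.per_sample_sd:.1f}",
            ]
            if self.unique.fraction_of_gbr is not None:
                lines.append(
                    f"unique share of gbr           "
                    f"{100 * self.unique.fraction_of_gbr:.1f}%"
                )
        lines.append("=" * 58)
        return "\n".join(lines)
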