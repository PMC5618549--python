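"""Multiplicity spectra and observation priors.

For a batch of ``n`` samples, the *multiplicity* of a gap-site is the
number of samples in which it was detected.  The multiplicity spectrum
``z_j`` counts gap-sites of each multiplicity ``j``; normalising it over
the observation probabilities ``p_j = j/n`` yields the observation prior,
the distribution from which the per-sample detection probability of a
random gap-site is drawn in the two-step observation model.

Real transcriptome batches show a characteristically U-shaped spectrum:
most gap-sites are seen either in (almost) all samples — junctions of
ubiquitously expressed genes — or only sporadically (rare splicing events
and aligner noise).  :func:`ushape_fraction` quantifies this.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .junction_io import SampleJunctions

__all__ = [
    "MultiplicitySpectrum",
    "ObservationPrior",
    "build_spectrum",
    "observation_prior",
    "ushape_fraction",
    "per_sample_multiplicity_table",
]


@dataclass(frozen=True)
class MultiplicitySpectrum:
    """Counts of gap-sites by cross-sample multiplicity.

    Parameters
    ----------
    n : int
        Batch size (number of samples).
    z : dict
        Map multiplicity ``j`` (1..n) -> number of gap-sites observed in
        exactly ``j`` samples.
    virtual : list of (float, float)
        Optional virtual bins ``(mu_v, m_v)``: ``m_v`` artificial events
        with fractional multiplicity ``mu_v`` in (0, 1), used by the
        finite-sampling bias correction.  Excluded from descriptive
        statistics.
    """

    n: int
    z: dict[int, int]
    virtual: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("batch size n must be >= 1")
        z = {int(j): int(c) for j, c in self.z.items() if c != 0}
        for j, c in z.items():
            if not 1 <= j <= self.n:
                raise ValueError(f"multiplicity {j} outside 1..{self.n}")
            if c < 0:
                raise ValueError(f"negative count z_{j}={c}")
        object.__setattr__(self, "z", z)
        virt = tuple((float(mu), float(m)) for mu, m in self.virtual)
        for mu, m in virt:
            if not 0.0 < mu < 1.0:
                raise ValueError(f"virtual multiplicity {mu} outside (0, 1)")
            if m < 0:
                raise ValueError(f"negative virtual count {m}")
        object.__setattr__(self, "virtual", virt)

    def total_sites(self) -> int:
        """Number of distinct gap-sites in the batch (integer bins only)."""
        return sum(self.z.values())

    def total_virtual(self) -> float:
        return sum(m for _, m in self.virtual)

    def multiplicities(self) -> np.ndarray:
        """All bin multiplicities (integer then virtual), as floats."""
        return np.array(sorted(self.z) + [mu for mu, _ in self.virtual], dtype=float)

    def counts(self) -> np.ndarray:
        """Counts matching :meth:`multiplicities`."""
        return np.array(
            [self.z[j] for j in sorted(self.z)] + [m for _, m in self.virtual],
            dtype=float,
        )

    def without_virtual(self) -> "MultiplicitySpectrum":
        return replace(self, virtual=())


@dataclass(frozen=True)
class ObservationPrior:
    """Discrete prior over per-sample observation probabilities.

    ``support`` holds the probabilities ``j/n`` (and ``mu_v/n`` for virtual
    bins), strictly increasing; ``mass`` the matching probabilities, which
    sum to one.
    """

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        support = np.asarray(self.support, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if support.shape != mass.shape or support.ndim != 1:
            raise ValueError("support and mass must be matching 1-d arrays")
        if np.any(support <= 0) or np.any(support > 1):
            raise ValueError("support values must lie in (0, 1]")
        if np.any(np.diff(support) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(mass < 0) or abs(mass.sum() - 1.0) > 1e-12:
            raise ValueError("mass must be nonnegative and sum to 1")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)


def _check_batch(samples: Sequence[SampleJunctions]) -> None:
    if not samples:
        raise ValueError("need at least one sample")
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_id in batch (double-counting risk)")


def _multiplicity_map(samples: Sequence[SampleJunctions]) -> dict:
    mult: dict = {}
    for s in samples:
        for key in s.sites:
            mult[key] = mult.get(key, 0) + 1
    return mult


def build_spectrum(
    samples: Sequence[SampleJunctions],
    category: Optional[str] = None,
) -> MultiplicitySpectrum:
    """Build the multiplicity spectrum of a batch.

    Parameters
    ----------
    samples : sequence of SampleJunctions
        The batch; sample ids must be distinct.
    category : str, optional
        If given, only sites carrying this label in at least one sample's
        ``category`` map are counted (stratified spectrum).
    """
    _check_batch(samples)
    if category is not None:
        labelled = set()
        for s in samples:
            if s.category:
                labelled.update(k for k, v in s.category.items() if v == category)
        samples = [
            SampleJunctions(s.sample_id, s.sites & labelled) for s in samples
        ]
    mult = _multiplicity_map(samples)
    z: dict[int, int] = {}
    for j in mult.values():
        z[j] = z.get(j, 0) + 1
    return MultiplicitySpectrum(n=len(samples), z=z)


def observation_prior(spectrum: MultiplicitySpectrum) -> ObservationPrior:
    """Normalise a spectrum into the observation prior.

    Each integer bin ``j`` contributes mass proportional to ``z_j`` at
    probability ``j/n``; virtual bins contribute at ``mu_v/n``.
    """
    total = spectrum.total_sites() + spectrum.total_virtual()
    if total <= 0:
        raise ValueError("empty spectrum has no observation prior")
    mult = spectrum.multiplicities()
    counts = spectrum.counts()
    order = np.argsort(mult)
    return ObservationPrior(
        support=mult[order] / spectrum.n, mass=counts[order] / total
    )


def ushape_fraction(spectrum: MultiplicitySpectrum, low: int, high: int) -> float:
    """Fraction of gap-sites with multiplicity below ``low`` or above ``high``.

    Quantifies the U-shape of the spectrum: mass at the extremes versus
    intermediate multiplicities.  Virtual bins are excluded.
    """
    if not 1 <= low <= high <= spectrum.n:
        raise ValueError(f"need 1 <= low <= high <= n, got {low}, {high}, n={spectrum.n}")
    total = spectrum.total_sites()
    if total == 0:
        raise ValueError("empty spectrum")
    extreme = sum(c for j, c in spectrum.z.items() if j < low or j > high)
    return extreme / total


def per_sample_multiplicity_table(
    samples: Sequence[SampleJunctions],
) -> pd.DataFrame:
    """Tabulate, per sample, its gap-sites by whole-batch multiplicity.

    Returns a DataFrame with one row per sample and one column per
    multiplicity ``j``; entry (s, j) is the number of sites of sample ``s``
    whose multiplicity across the whole batch equals ``j``.  Row sums equal
    per-sample site counts; column ``j`` sums to ``j * z_j``.  Summary rows
    (median, quartiles, min, max over samples) are attached via
    ``DataFrame.attrs['summary']``.
    """
    _check_batch(samples)
    mult = _multiplicity_map(samples)
    n = len(samples)
    js = np.arange(1, n + 1)
    table = pd.DataFrame(
        0, index=[s.sample_id for s in samples], columns=js, dtype=int
    )
    for s in samples:
        for key in s.sites:
            table.loc[s.sample_id, mult[key]] += 1
    summary = pd.DataFrame(
        {
            "median": table.median(),
            "q25": table.quantile(0.25),
            "q75": table.quantile(0.75),
            "min": table.min(),
            "max": table.max(),
        }
    )
    table.attrs["summary"] = summary
    return table
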