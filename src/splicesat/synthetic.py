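"""Synthetic junction batches under the independence model.

Each synthetic gap-site receives a true per-sample observation
probability ``p`` — either from explicit (count, p) classes or from a
U-shaped Beta-mixture prior — and is then present in each of ``n``
samples independently with probability ``p``.  This reproduces the
two-step generative model (draw ``p`` from the prior, then Bernoulli
observations) and gives every downstream operation a batch with known
ground truth.

The default prior, ``0.85 * Beta(0.3, 8) + 0.15 * Beta(8, 0.3)``, is a
stand-in for the empirical U-shape of real transcriptome batches: most
sites are either near-ubiquitous (constitutive junctions) or sporadic
(rare splicing and alignment noise).  At ``n = 54`` roughly three
quarters of the realised site multiplicities fall below 5 or above 50,
comparable to what real fibroblast batches show.  No parametric form is
claimed for real priors; see the methods notes for what this generator
does and does not emulate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .junction_io import GapSiteKey, SampleJunctions
from .model import DEFAULT_MU_V, predict_curve
from .spectrum import build_spectrum
from .subsample import (
    draw_subbatches,
    median_relative_deviation,
    smooth_curve,
    terminal_slope,
)

__all__ = [
    "SyntheticBatchSpec",
    "ModelCheckReport",
    "generate_batch",
    "write_fixture",
    "empirical_vs_model_check",
]

#: Default U-shape prior: (weight, alpha, beta) Beta-mixture components.
USHAPE_MIXTURE = ((0.85, 0.3, 8.0), (0.15, 8.0, 0.3))


@dataclass(frozen=True)
class SyntheticBatchSpec:
    """Recipe for one synthetic batch.

    Exactly one of ``classes`` (explicit (n_sites, p) site classes) or
    ``n_sites`` (sites drawn from the ``mixture`` prior) must be given.
    ``genome`` is (number of sequences, lowest position, highest position)
    for coordinate assignment; positions start high enough that both
    supported file dialects can represent every site.
    """

    n_samples: int
    classes: Optional[tuple[tuple[int, float], ...]] = None
    n_sites: Optional[int] = None
    mixture: tuple[tuple[float, float, float], ...] = USHAPE_MIXTURE
    genome: tuple[int, int, int] = (24, 1000, 50_000_000)
    intron_length: tuple[int, int] = (60, 5000)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if (self.classes is None) == (self.n_sites is None):
            raise ValueError("give exactly one of classes or n_sites")
        if self.classes is not None:
            for k, p in self.classes:
                if k < 0 or not 0.0 < p <= 1.0:
                    raise ValueError(f"bad class (n_sites={k}, p={p})")
            if sum(k for k, _ in self.classes) == 0:
                raise ValueError("zero total sites")
        else:
            if self.n_sites <= 0:
                raise ValueError("zero total sites")
            w = sum(c[0] for c in self.mixture)
            if abs(w - 1.0) > 1e-9:
                raise ValueError(f"mixture weights sum to {w}, not 1")


def _draw_probabilities(spec: SyntheticBatchSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.classes is not None:
        return np.repeat(
            [p for _, p in spec.classes], [k for k, _ in spec.classes]
        )
    weights = np.array([c[0] for c in spec.mixture])
    comp = rng.choice(len(spec.mixture), size=spec.n_sites, p=weights)
    p = np.empty(spec.n_sites)
    for i, (_, a, b) in enumerate(spec.mixture):
        sel = comp == i
        p[sel] = rng.beta(a, b, size=int(sel.sum()))
    # Beta draws can round to exactly 0; such sites are unobservable and
    # outside the model's support, so nudge them to the smallest positive p.
    return np.clip(p, 1e-12, 1.0)


def _draw_keys(n: int, spec: SyntheticBatchSpec, rng: np.random.Generator) -> list[GapSiteKey]:
    n_seqs, lo, hi = spec.genome
    len_lo, len_hi = spec.intron_length
    keys: set[GapSiteKey] = set()
    while len(keys) < n:
        need = n - len(keys)
        seq = rng.integers(1, n_seqs + 1, size=need)
        start = rng.integers(lo, hi, size=need)
        length = rng.integers(len_lo, len_hi + 1, size=need)
        strand = rng.choice(["+", "-"], size=need)
        for s, st, ln, sd in zip(seq, start, length, strand):
            keys.add(GapSiteKey(f"chr{s}", int(st), int(st + ln - 1), str(sd)))
    return sorted(keys)


def generate_batch(
    spec: SyntheticBatchSpec,
) -> tuple[list[SampleJunctions], dict[GapSiteKey, float]]:
    """Generate a batch of samples plus the ground-truth p of every site.

    Sites observed in no sample are absent from the returned samples but
    kept in ``truth``, mirroring the fact that real batches never show the
    unobserved part of the site population.
    """
    rng = np.random.default_rng(spec.seed)
    p = _draw_probabilities(spec, rng)
    keys = _draw_keys(len(p), spec, rng)
    truth = dict(zip(keys, p.tolist()))
    presence = rng.random((len(p), spec.n_samples)) < p[:, None]
    samples = []
    for col in range(spec.n_samples):
        sites = {keys[i] for i in np.flatnonzero(presence[:, col])}
        samples.append(SampleJunctions(sample_id=f"sample{col + 1:02d}", sites=sites))
    return samples, truth


_BED_FLANK = 20  # exonic anchor length written on each side of the intron


def write_fixture(
    samples: Sequence[SampleJunctions], directory, format: str = "star_sj"
) -> list[str]:
    """Write one junction file per sample in the requested dialect.

    ``format`` is ``"star_sj"`` (STAR ``SJ.out.tab``) or ``"tophat_bed"``
    (TopHat ``junctions.bed``).  Re-reading the files reconstructs the
    same site sets.  Missing support values are written as 1 read.
    Returns the written paths.
    """
    os.makedirs(directory, exist_ok=True)
    strand_code = {".": "0", "+": "1", "-": "2"}
    paths = []
    for s in samples:
        support = s.support or {}
        if format == "star_sj":
            path = os.path.join(directory, f"{s.sample_id}.SJ.out.tab")
            with open(path, "w") as fh:
                for key in sorted(s.sites):
                    reads = support.get(key, 1)
                    fh.write(
                        f"{key.seqid}\t{key.intron_start}\t{key.intron_end}\t"
                        f"{strand_code[key.strand]}\t0\t0\t{reads}\t0\t{_BED_FLANK}\n"
                    )
        elif format == "tophat_bed":
            path = os.path.join(directory, f"{s.sample_id}.junctions.bed")
            with open(path, "w") as fh:
                fh.write(f'track name=junctions description="{s.sample_id}"\n')
                for i, key in enumerate(sorted(s.sites)):
                    if key.intron_start <= _BED_FLANK:
                        raise ValueError(
                            f"intron start {key.intron_start} too close to the "
                            f"sequence start for a {_BED_FLANK} nt BED anchor"
                        )
                    reads = support.get(key, 1)
                    chrom_start = key.intron_start - 1 - _BED_FLANK
                    chrom_end = key.intron_end + _BED_FLANK
                    second_start = key.intron_end - chrom_start
                    fh.write(
                        f"{key.seqid}\t{chrom_start}\t{chrom_end}\tJUNC{i + 1:08d}\t"
                        f"{reads}\t{key.strand}\t{chrom_start}\t{chrom_end}\t255,0,0\t2\t"
                        f"{_BED_FLANK},{_BED_FLANK}\t0,{second_start}\n"
                    )
        else:
            raise ValueError(f"unknown format {format!r}")
        paths.append(path)
    return paths


@dataclass(frozen=True)
class ModelCheckReport:
    """Raw vs corrected model agreement with resampled observations."""

    raw_deviation_pct: float
    corrected_deviation_pct: float
    gbr: float
    total_sites: int
    n_samples: int


def empirical_vs_model_check(
    spec: SyntheticBatchSpec,
    nu_grid: Optional[Sequence[int]] = None,
    n_reps: int = 200,
    span: float = 0.75,
    mu_v: float = DEFAULT_MU_V,
) -> ModelCheckReport:
    """Full-pipeline consistency check on one synthetic batch.

    Generates the batch, builds its spectrum, resamples sub-batches,
    smooths the empirical curve, and reports the median relative deviation
    of the raw and corrected model predictions from it, plus the basal
    rate of the smoothed curve.
    """
    if spec.n_samples < 10:
        raise ValueError("model check needs n_samples >= 10")
    samples, _ = generate_batch(spec)
    spectrum = build_spectrum(samples)
    results = draw_subbatches(samples, n_reps=n_reps, seed=spec.seed + 1)
    smoothed = smooth_curve(results, span=span)
    grid = list(nu_grid) if nu_grid is not None else [int(v) for v in smoothed.nu]
    raw = predict_curve(spectrum, grid, corrected=False)
    corrected = predict_curve(spectrum, grid, corrected=True, mu_v=mu_v)
    return ModelCheckReport(
        raw_deviation_pct=median_relative_deviation(raw, smoothed),
        corrected_deviation_pct=median_relative_deviation(corrected, smoothed),
        gbr=terminal_slope(smoothed),
        total_sites=spectrum.total_sites(),
        n_samples=spec.n_samples,
    )
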