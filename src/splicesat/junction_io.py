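"""Reading and writing splice-junction tables.

Junctions ("gap-sites") are alignment gaps reported by spliced aligners.
Two input dialects are supported:

* STAR ``SJ.out.tab`` — 9 tab-separated columns with 1-based, inclusive
  intron coordinates (first and last intronic base).
* TopHat ``junctions.bed`` — BED12 with 0-based half-open coordinates and
  two blocks flanking the intron.

Both are normalised to a single canonical key space
(:class:`GapSiteKey`: 1-based inclusive intron coordinates, STAR style) so
that batches produced by different aligners merge on identical keys.

The package's own tabular output (multiplicity spectra) is plain TSV with a
``# n=<batch size>`` header line.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

__all__ = [
    "GapSiteKey",
    "SampleJunctions",
    "JunctionParseError",
    "read_star_sj",
    "read_tophat_bed",
    "write_spectrum_table",
    "read_spectrum_table",
]


class JunctionParseError(ValueError):
    """Raised for malformed junction or spectrum files; names file and line."""

    def __init__(self, path, lineno: int, message: str):
        self.path = os.fspath(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


class GapSiteKey(NamedTuple):
    """Genomic identity of one putative splice site.

    Coordinates are 1-based and inclusive: ``intron_start`` is the first
    intronic base, ``intron_end`` the last.  Field order makes keys sort
    naturally by (seqid, intron_start, intron_end, strand).
    """

    seqid: str
    intron_start: int
    intron_end: int
    strand: str  # '+', '-' or '.'


_STAR_STRAND = {"0": ".", "1": "+", "2": "-"}


@dataclass
class SampleJunctions:
    """One sample's set of gap-sites with optional per-site metadata.

    Parameters
    ----------
    sample_id : str
        Unique identifier of the sample within a batch.
    sites : set of GapSiteKey
        The gap-sites detected in this sample.
    support : dict, optional
        Per-site aligned-read counts.
    n_aligns : int, optional
        Total alignment count of the sample (alignment depth).
    category : dict, optional
        Per-site text labels, e.g. an externally computed gap-quality
        level; used only for stratified counting.
    """

    sample_id: str
    sites: set[GapSiteKey]
    support: Optional[dict[GapSiteKey, int]] = None
    n_aligns: Optional[int] = None
    category: Optional[dict[GapSiteKey, str]] = None

    def __post_init__(self):
        self.sites = set(self.sites)
        for name in ("support", "category"):
            mapping = getattr(self, name)
            if mapping is not None:
                extra = set(mapping) - self.sites
                if extra:
                    raise ValueError(
                        f"{name} contains {len(extra)} keys absent from sites"
                    )

    def __len__(self) -> int:
        return len(self.sites)


def read_star_sj(path, min_reads: int = 1, count_multimappers: bool = False) -> SampleJunctions:
    """Read a STAR ``SJ.out.tab`` file.

    Columns: seqid, intron start, intron end, strand code (0 undefined,
    1 '+', 2 '-'), intron motif, annotated flag, unique reads, multimapping
    reads, maximum spliced overhang.  Sites whose read support (unique
    reads, plus multimapping reads when ``count_multimappers``) falls below
    ``min_reads`` are dropped.
    """
    sites: set[GapSiteKey] = set()
    support: dict[GapSiteKey, int] = {}
    sample_id = _strip_ext(path, (".tab", ".tsv", ".txt"))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 9:
                raise JunctionParseError(
                    path, lineno, f"expected >=9 columns, got {len(fields)}"
                )
            try:
                start = int(fields[1])
                end = int(fields[2])
                uniq = int(fields[6])
                multi = int(fields[7])
            except ValueError as exc:
                raise JunctionParseError(path, lineno, f"non-integer field: {exc}") from None
            if start > end:
                raise JunctionParseError(
                    path, lineno, f"intron start {start} > end {end}"
                )
            strand = _STAR_STRAND.get(fields[3])
            if strand is None:
                raise JunctionParseError(path, lineno, f"bad strand code {fields[3]!r}")
            reads = uniq + multi if count_multimappers else uniq
            if reads < min_reads:
                continue
            key = GapSiteKey(fields[0], start, end, strand)
            sites.add(key)
            support[key] = reads
    return SampleJunctions(sample_id=sample_id, sites=sites, support=support)


def read_tophat_bed(path, min_reads: int = 1) -> SampleJunctions:
    """Read a TopHat ``junctions.bed`` file (BED12, two blocks per record).

    BED coordinates are 0-based half-open; each record's two blocks are the
    exonic anchors flanking the intron, so in 1-based inclusive terms::

        intron_start = chromStart + blockSizes[0] + 1
        intron_end   = chromStart + blockStarts[1]

    The BED score column is taken as read support and filtered by
    ``min_reads``.  ``track``/``browser``/comment lines are skipped.
    """
    sites: set[GapSiteKey] = set()
    support: dict[GapSiteKey, int] = {}
    sample_id = _strip_ext(path, (".bed",))
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise JunctionParseError(
                    path, lineno, f"expected 12 BED columns, got {len(fields)}"
                )
            try:
                chrom_start = int(fields[1])
                score = int(float(fields[4]))
                block_count = int(fields[9])
                block_sizes = [int(v) for v in fields[10].rstrip(",").split(",")]
                block_starts = [int(v) for v in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise JunctionParseError(path, lineno, f"bad numeric field: {exc}") from None
            if block_count != 2 or len(block_sizes) != 2 or len(block_starts) != 2:
                raise JunctionParseError(
                    path, lineno, f"junction records need exactly 2 blocks, got {block_count}"
                )
            if block_starts[1] <= block_sizes[0]:
                raise JunctionParseError(path, lineno, "empty or negative intron")
            strand = fields[5] if fields[5] in {"+", "-", "."} else "."
            if score < min_reads:
                continue
            key = GapSiteKey(
                fields[0],
                chrom_start + block_sizes[0] + 1,
                chrom_start + block_starts[1],
                strand,
            )
            sites.add(key)
            support[key] = score
    return SampleJunctions(sample_id=sample_id, sites=sites, support=support)


def write_spectrum_table(spectrum, path) -> None:
    """Write a multiplicity spectrum as TSV.

    Format: one ``# n=<batch size>`` comment, a header row, then one row per
    bin with columns ``multiplicity`` (decimal, so fractional virtual bins
    are representable) and ``count``.
    """
    with open(path, "w") as fh:
        fh.write(f"# n={spectrum.n}\n")
        fh.write("multiplicity\tcount\n")
        for j in sorted(spectrum.z):
            fh.write(f"{j}\t{spectrum.z[j]}\n")
        for mu_v, m_v in spectrum.virtual:
            fh.write(f"{mu_v!r}\t{m_v!r}\n")


def read_spectrum_table(path):
    """Read a TSV spectrum written by :func:`write_spectrum_table`.

    Rows with integral multiplicity populate the integer bins; rows with
    fractional multiplicity in (0, 1) become virtual bins.
    """
    from .spectrum import MultiplicitySpectrum

    n = None
    z: dict[int, int] = {}
    virtual: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("n="):
                    n = int(body[2:])
                continue
            fields = line.split("\t")
            if fields[0] == "multiplicity":
                if fields[:2] != ["multiplicity", "count"]:
                    raise JunctionParseError(path, lineno, f"unknown header {fields!r}")
                continue
            if len(fields) != 2:
                raise JunctionParseError(path, lineno, "expected 2 columns")
            try:
                mult = float(fields[0])
            except ValueError:
                raise JunctionParseError(path, lineno, f"bad multiplicity {fields[0]!r}") from None
            if mult == int(mult) and mult >= 1:
                count = int(fields[1]) if "." not in fields[1] else int(float(fields[1]))
                if count < 0:
                    raise JunctionParseError(path, lineno, "negative count")
                z[int(mult)] = count
            else:
                m_v = float(fields[1])
                if m_v < 0:
                    raise JunctionParseError(path, lineno, "negative count")
                virtual.append((mult, m_v))
    if n is None:
        raise JunctionParseError(path, 0, "missing '# n=' header")
    return MultiplicitySpectrum(n=n, z=z, virtual=virtual)


def _strip_ext(path, exts: Iterable[str]) -> str:
    base = os.path.basename(os.fspath(path))
    for ext in exts:
        if base.endswith(ext):
            return base[: -len(ext)]
    return base
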