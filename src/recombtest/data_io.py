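"""Haplotype data containers and text I/O.

Phased biallelic haplotypes are held as an ``n x S`` 0/1 matrix with
physical SNP coordinates in kb.  The primary interchange format is the
output dialect of Hudson's ``ms`` coalescent simulator (``segsites:`` /
``positions:`` blocks with positions as fractions of the region); a plain
matrix format with explicit kb coordinates is also supported.  Loci can be
cut into overlapping fixed-size SNP windows for segment-wise testing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, TextIO

import numpy as np

__all__ = [
    "HaplotypeMatrix",
    "SegmentSpec",
    "MSParseError",
    "read_ms",
    "write_ms",
    "read_plain",
    "write_plain",
    "segment_haplotypes",
]


class MSParseError(ValueError):
    """Raised when an ms-format block is structurally invalid."""


@dataclass
class HaplotypeMatrix:
    """``n`` phased binary haplotypes typed at ``S`` ordered SNP positions.

    Parameters
    ----------
    alleles
        ``(n, S)`` integer array with entries in {0, 1}.
    positions
        Strictly increasing physical coordinates in kb, within ``[0, L]``.
    region_length
        Physical length ``L`` of the surveyed region in kb.
    labels
        Optional per-haplotype identifiers.
    """

    alleles: np.ndarray
    positions: np.ndarray
    region_length: float
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(np.asarray(self.alleles, dtype=np.int8))
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D matrix")
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 1 or self.positions.shape[0] != self.alleles.shape[1]:
            raise ValueError("positions must match the number of SNP columns")
        bad = (self.alleles != 0) & (self.alleles != 1)
        if bad.any():
            raise ValueError("allele entries must be 0 or 1")
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < 0 or self.positions[-1] > self.region_length:
                raise ValueError("positions must lie within [0, region_length]")
        if self.labels is not None and len(self.labels) != self.alleles.shape[0]:
            raise ValueError("labels must match the number of haplotypes")

    @property
    def n(self) -> int:
        """Number of haplotypes."""
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        """Number of segregating sites ``S``."""
        return self.alleles.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeMatrix):
            return NotImplemented
        return (
            np.array_equal(self.alleles, other.alleles)
            and np.allclose(self.positions, other.positions)
            and np.isclose(self.region_length, other.region_length)
        )


@dataclass(frozen=True)
class SegmentSpec:
    """Overlapping SNP-window segmentation of a locus.

    Defaults follow the common convention of 20-SNP windows with 15 SNPs
    shared between adjacent windows.
    """

    window: int = 20
    overlap: int = 15

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.window:
            raise ValueError("require 0 <= overlap < window")


def _as_stream(source: str | TextIO) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_ms(source: str | TextIO, region_length: float) -> list[HaplotypeMatrix]:
    """Parse ms-format text into one :class:`HaplotypeMatrix` per replicate.

    Lines before the first ``//`` (the command echo and seeds) are ignored.
    Positions, given by ms as fractions of the unit interval, are rescaled
    to kb by ``region_length``.
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    stream = _as_stream(source)
    lines = stream.read().splitlines()
    # replicate blocks start at '//'
    starts = [i for i, ln in enumerate(lines) if ln.strip().startswith("//")]
    if not starts:
        raise MSParseError("no '//' replicate separator found")
    out: list[HaplotypeMatrix] = []
    bounds = starts + [len(lines)]
    for rep, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        block = lines[lo + 1 : hi]
        out.append(_parse_block(block, rep, lo + 1, region_length))
    return out


def _parse_block(
    block: list[str], rep: int, offset: int, region_length: float
) -> HaplotypeMatrix:
    def err(msg: str, i: int) -> MSParseError:
        return MSParseError(f"replicate {rep}, line {offset + i + 1}: {msg}")

    seg: int | None = None
    positions: np.ndarray | None = None
    rows: list[str] = []
    for i, raw in enumerate(block):
        ln = raw.strip()
        if not ln:
            continue
        if ln.startswith("segsites:"):
            try:
                seg = int(ln.split(":", 1)[1])
            except ValueError:
                raise err("unreadable segsites count", i) from None
        elif ln.startswith("positions:"):
            try:
                positions = np.array(
                    [float(tok) for tok in ln.split(":", 1)[1].split()]
                )
            except ValueError:
                raise err("unreadable positions", i) from None
            if seg is not None and positions.size != seg:
                raise err(
                    f"{positions.size} positions but segsites: {seg}", i
                )
            if positions.size and np.any(np.diff(positions) <= 0):
                raise err("positions not strictly increasing", i)
        else:
            if seg is None:
                raise err("haplotype row before 'segsites:'", i)
            if set(ln) - {"0", "1"}:
                raise err("haplotype row contains non-0/1 characters", i)
            if len(ln) != seg:
                raise err(f"row length {len(ln)} != segsites {seg}", i)
            rows.append(ln)
    if seg is None:
        raise MSParseError(f"replicate {rep}: missing 'segsites:' line")
    if seg == 0:
        alleles = np.zeros((len(rows), 0), dtype=np.int8)
        positions = np.zeros(0)
    else:
        if positions is None:
            raise MSParseError(f"replicate {rep}: missing 'positions:' line")
        alleles = np.array([[int(c) for c in r] for r in rows], dtype=np.int8)
    return HaplotypeMatrix(
        alleles=alleles,
        positions=positions * region_length,
        region_length=region_length,
    )


def write_ms(
    data: Iterable[HaplotypeMatrix], stream: TextIO | None = None
) -> str | None:
    """Serialise haplotype matrices as ms-format text.

    ``read_ms(write_ms(x), L)`` reproduces the alleles exactly and the
    positions to within ``1e-6 * L`` (positions are printed with six
    decimals as fractions of the region).
    """
    buf = stream if stream is not None else io.StringIO()
    for mat in data:
        buf.write("//\n")
        buf.write(f"segsites: {mat.n_sites}\n")
        if mat.n_sites:
            frac = mat.positions / mat.region_length
            buf.write("positions: " + " ".join(f"{p:.6f}" for p in frac) + "\n")
        for row in mat.alleles:
            buf.write("".join("1" if a else "0" for a in row) + "\n")
        buf.write("\n")
    if stream is None:
        return buf.getvalue()  # type: ignore[union-attr]
    return None


def read_plain(source: str | TextIO) -> HaplotypeMatrix:
    """Read the plain matrix format: header ``n S L``, one line of S
    positions in kb, then n rows of S characters in {0, 1}."""
    stream = _as_stream(source)
    lines = [ln for ln in stream.read().splitlines() if ln.strip()]
    if not lines:
        raise MSParseError("empty input")
    try:
        n, S, L = lines[0].split()
        n, S, L = int(n), int(S), float(L)
    except ValueError:
        raise MSParseError("header must be 'n S L'") from None
    if S > 0:
        positions = np.array([float(t) for t in lines[1].split()])
        rows = lines[2 : 2 + n]
    else:
        positions = np.zeros(0)
        rows = lines[1 : 1 + n]
    if len(rows) != n:
        raise MSParseError(f"expected {n} haplotype rows, found {len(rows)}")
    alleles = np.array([[int(c) for c in r.strip()] for r in rows], dtype=np.int8)
    if S == 0:
        alleles = alleles.reshape(n, 0)
    return HaplotypeMatrix(alleles=alleles, positions=positions, region_length=L)


def write_plain(mat: HaplotypeMatrix, stream: TextIO | None = None) -> str | None:
    buf = stream if stream is not None else io.StringIO()
    buf.write(f"{mat.n} {mat.n_sites} {mat.region_length:g}\n")
    if mat.n_sites:
        buf.write(" ".join(f"{p:.6f}" for p in mat.positions) + "\n")
    for row in mat.alleles:
        buf.write("".join("1" if a else "0" for a in row) + "\n")
    if stream is None:
        return buf.getvalue()  # type: ignore[union-attr]
    return None


def segment_haplotypes(
    data: HaplotypeMatrix, spec: SegmentSpec = SegmentSpec()
) -> list[HaplotypeMatrix]:
    """Cut a locus into overlapping SNP windows.

    Windows start at SNP offsets ``0, step, 2*step, ...`` with
    ``step = window - overlap``; each holds ``window`` SNPs except the last,
    which absorbs any remainder of fewer than ``step`` trailing SNPs (so a
    41-SNP locus at window 20 / overlap 15 yields five segments of sizes
    20, 20, 20, 20 and 21).  Segment positions are re-anchored to the
    segment's first SNP and its physical length is the first-to-last SNP
    distance.
    """
    S = data.n_sites
    if S < spec.window:
        raise ValueError(
            f"locus has {S} SNPs < window {spec.window}; "
            "analyse the whole locus instead of segmenting"
        )
    step = spec.window - spec.overlap
    starts = list(range(0, S - spec.window + 1, step))
    segments: list[HaplotypeMatrix] = []
    for idx, s0 in enumerate(starts):
        s1 = s0 + spec.window
        if idx == len(starts) - 1:
            s1 = S  # absorb trailing remainder (< step SNPs)
        pos = data.positions[s0:s1]
        anchored = pos - pos[0]
        length = float(anchored[-1]) if anchored[-1] > 0 else data.region_length
        segments.append(
            HaplotypeMatrix(
                alleles=data.alleles[:, s0:s1],
                positions=anchored,
                region_length=length,
            )
        )
    return segments
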