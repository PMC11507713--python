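"""Diploid sequence encoding, window extraction, peak pairing and coverage
normalization.

The central representation is the *two-hot* matrix: an unphased diploid
sequence is encoded per position as the sum of the one-hot encodings of the
two allelic nucleotides, so every row of the L x 4 matrix (channel order
A, C, G, T) sums to 2. For example the diploid sequence ``AYCR`` (A; C/T
het; C; A/G het) encodes as::

    [[2, 0, 0, 0],
     [0, 1, 0, 1],
     [0, 2, 0, 0],
     [1, 0, 1, 0]]

Unknown bases (``N``) become all-zero rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BASES",
    "GenomicWindow",
    "CoverageWindow",
    "two_hot_encode",
    "two_hot_encode_iupac",
    "decode_two_hot",
    "mask_variants",
    "extract_window",
    "pair_divergent_peaks",
    "rpm_factor",
    "rpm_normalize",
]

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: IUPAC codes representing a diploid genotype as an unordered base pair.
IUPAC_DIPLOID = {
    "A": "AA", "C": "CC", "G": "GG", "T": "TT",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
}


@dataclass(frozen=True)
class GenomicWindow:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid window [{self.start}, {self.end})")

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class CoverageWindow:
    """Strand-specific base-resolution coverage over a genomic window."""

    plus: np.ndarray
    minus: np.ndarray
    window: GenomicWindow

    def __post_init__(self) -> None:
        if len(self.plus) != self.window.width or len(self.minus) != self.window.width:
            raise ValueError("coverage length does not match window width")
        if (np.asarray(self.plus) < 0).any() or (np.asarray(self.minus) < 0).any():
            raise ValueError("coverage must be nonnegative")

    def concatenated(self) -> np.ndarray:
        return np.concatenate([self.plus, self.minus]).astype(np.float64)


def _one_hot_rows(seq: str) -> np.ndarray:
    out = np.zeros((len(seq), 4), dtype=np.int64)
    for i, b in enumerate(seq.upper()):
        if b == "N":
            continue
        if b not in _BASE_IDX:
            raise ValueError(f"unknown base {b!r} at position {i} (no masking policy)")
        out[i, _BASE_IDX[b]] = 1
    return out


def two_hot_encode(reference_window: str,
                   dosages: np.ndarray | None = None,
                   alt_alleles: dict[int, str] | None = None) -> np.ndarray:
    """Encode an unphased diploid window as an L x 4 two-hot matrix.

    Parameters
    ----------
    reference_window
        Reference bases over the window (A/C/G/T; N allowed, yields an
        all-zero row).
    dosages
        Per-position count of alternate-allele copies in {0, 1, 2}.
        ``None`` means homozygous reference everywhere.
    alt_alleles
        Mapping position -> alternate base, required wherever dosage > 0.
    """
    ref = _one_hot_rows(reference_window)
    if dosages is None:
        return 2 * ref
    dosages = np.asarray(dosages, dtype=np.int64)
    if dosages.shape != (len(reference_window),):
        raise ValueError("dosages must have one entry per window position")
    if ((dosages < 0) | (dosages > 2)).any():
        raise ValueError("dosages must be in {0, 1, 2}")
    out = (2 - dosages)[:, None] * ref
    alt_alleles = alt_alleles or {}
    for pos in np.nonzero(dosages)[0]:
        alt = alt_alleles.get(int(pos))
        if alt is None:
            raise ValueError(f"dosage > 0 at position {pos} but no alternate allele given")
        out[pos] += dosages[pos] * _one_hot_rows(alt)[0]
    return out


def two_hot_encode_iupac(seq: str) -> np.ndarray:
    """Encode a diploid sequence written with IUPAC heterozygote codes."""
    out = np.zeros((len(seq), 4), dtype=np.int64)
    for i, code in enumerate(seq.upper()):
        if code == "N":
            continue
        pair = IUPAC_DIPLOID.get(code)
        if pair is None:
            raise ValueError(f"unsupported IUPAC code {code!r} at position {i}")
        for b in pair:
            out[i, _BASE_IDX[b]] += 1
    return out


def decode_two_hot(matrix: np.ndarray) -> str:
    """Decode a homozygous two-hot matrix back to its base string."""
    matrix = np.asarray(matrix)
    out = []
    for i, row in enumerate(matrix):
        if row.sum() == 0:
            out.append("N")
        elif row.max() == 2 and row.sum() == 2:
            out.append(BASES[int(row.argmax())])
        else:
            raise ValueError(f"row {i} is not homozygous: {row.tolist()}")
    return "".join(out)


def mask_variants(reference_window: str, variant_positions) -> str:
    """Variant masking: genotypes are ignored and the window encodes as
    homozygous reference. Returns the reference bases unchanged."""
    for pos in variant_positions:
        if not 0 <= pos < len(reference_window):
            raise ValueError(f"variant position {pos} outside window of length "
                             f"{len(reference_window)}")
    return reference_window


def extract_window(chrom: str, center: int, chrom_length: int, width: int = 1000,
                   jitter_max: int = 250,
                   rng: np.random.Generator | None = None) -> GenomicWindow:
    """Window of ``width`` bp around ``center``, start jittered uniformly in
    [-jitter_max, +jitter_max]. Raises if the window leaves the chromosome."""
    jitter = 0
    if jitter_max > 0:
        rng = rng or np.random.default_rng()
        jitter = int(rng.integers(-jitter_max, jitter_max + 1))
    start = center - width // 2 + jitter
    end = start + width
    if start < 0 or end > chrom_length:
        raise ValueError(
            f"window [{start}, {end}) around {chrom}:{center} exceeds chromosome bounds")
    return GenomicWindow(chrom, start, end)


def _summit(start: int, end: int, track: np.ndarray | None) -> int:
    if track is None:
        return (start + end) // 2
    return start + int(np.argmax(track[start:end]))  # ties -> leftmost


def pair_divergent_peaks(peaks: pd.DataFrame, max_distance: int = 200,
                         coverage: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
                         ) -> pd.DataFrame:
    """Pair unidirectional peaks with an opposite-strand peak within
    ``max_distance`` bp (gap between nearest interval edges; overlapping
    intervals have gap 0).

    Each peak is matched to its nearest qualifying opposite-strand peak
    (ties broken by leftmost start); mutual matches define one divergent
    element whose center is the midpoint of the two peak summits. Summits
    are coverage argmaxes when per-strand ``coverage`` tracks are supplied,
    interval midpoints otherwise.

    Parameters
    ----------
    peaks
        DataFrame with columns chrom, start, end, strand ('+'/'-').
    """
    required = {"chrom", "start", "end", "strand"}
    if not required.issubset(peaks.columns):
        raise ValueError(f"peaks must have columns {sorted(required)}")
    rows = []
    for chrom, group in peaks.groupby("chrom", sort=True):
        plus = group[group.strand == "+"].sort_values(["start", "end"]).reset_index(drop=True)
        minus = group[group.strand == "-"].sort_values(["start", "end"]).reset_index(drop=True)
        if plus.empty or minus.empty:
            continue

        def nearest(a_row, others):
            gaps = np.maximum(others.start.values - int(a_row.end),
                              int(a_row.start) - others.end.values)
            gaps = np.maximum(gaps, 0)
            ok = gaps <= max_distance
            if not ok.any():
                return None
            cand = np.nonzero(ok)[0]
            return int(cand[np.argmin(gaps[cand])])  # ties -> leftmost (sorted)

        plus_match = [nearest(r, minus) for r in plus.itertuples()]
        minus_match = [nearest(r, plus) for r in minus.itertuples()]
        for pi, mi in enumerate(plus_match):
            if mi is not None and minus_match[mi] == pi:
                cov = coverage.get(chrom) if coverage else None
                ps = _summit(int(plus.start[pi]), int(plus.end[pi]),
                             cov[0] if cov else None)
                ms = _summit(int(minus.start[mi]), int(minus.end[mi]),
                             cov[1] if cov else None)
                rows.append({"chrom": chrom, "center": (ps + ms) // 2,
                             "plus_summit": ps, "minus_summit": ms})
    return pd.DataFrame(rows, columns=["chrom", "center", "plus_summit", "minus_summit"])


def rpm_factor(coverage: dict[str, tuple[np.ndarray, np.ndarray]]) -> float:
    """Reads-per-million scale factor for a full-genome coverage library."""
    total = sum(float(np.sum(p)) + float(np.sum(m)) for p, m in coverage.values())
    if total <= 0:
        raise ValueError("cannot RPM-normalize a zero-total library")
    return 1e6 / total


def rpm_normalize(coverage: dict[str, tuple[np.ndarray, np.ndarray]]
                  ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Scale coverage so the genome-wide total over both strands is 1e6."""
    f = rpm_factor(coverage)
    return {chrom: (np.asarray(p, dtype=np.float64) * f, np.asarray(m, dtype=np.float64) * f)
            for chrom, (p, m) in coverage.items()}
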