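"""Target-window extraction and one-hot encoding.

Every model input is a fixed-geometry 60 bp window around a Cas9 target: the
NGG protospacer-adjacent motif (PAM) occupies 1-based window positions 33-35,
which puts the blunt cut site (3 bp upstream of the PAM) between positions 30
and 31 — i.e. at the window centre.  Concretely the window covers 32 bases
left of the PAM's first base and 27 bases right of it (PAM included), and
missing genomic flank is padded with 'N'.

Coordinates are 0-based half-open everywhere in code; 1-based positions
appear only in human-facing text and reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import CoordinateError, EncodingError, InputError

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 60
PAM_OFFSET = 32          # 0-based index of the PAM's first base in the window
LEFT_FLANK = PAM_OFFSET  # bases left of the PAM's first base
RIGHT_FLANK = WINDOW_LENGTH - PAM_OFFSET  # PAM first base + 27 more

ALPHABET = "ACGT"
_ROW = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_window(window: str) -> str:
    window = window.upper()
    if len(window) != WINDOW_LENGTH:
        raise EncodingError(f"window length {len(window)} != {WINDOW_LENGTH}")
    for i, ch in enumerate(window):
        if ch not in "ACGTN":
            raise EncodingError(f"invalid character {ch!r} at window position {i + 1}")
    return window


@dataclass(frozen=True)
class TargetSite:
    """A 60 bp model window plus optional genomic provenance.

    ``pam_start_genomic`` is the 0-based forward-strand coordinate of the
    base that is the PAM's first base *in the window's frame* (for minus
    strand sites, the forward-strand position whose complement starts the
    PAM).  Padding-only windows carry N's and may lack a valid GG.
    """

    window: str
    site_id: str = ""
    chrom: str | None = None
    pam_start_genomic: int | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "window", _validate_window(self.window))
        if self.strand not in "+-":
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def has_valid_pam(self) -> bool:
        """True when window positions 34-35 (1-based) are both 'G'."""
        return self.window[PAM_OFFSET + 1: PAM_OFFSET + 3] == "GG"

    @property
    def is_padded(self) -> bool:
        return "N" in self.window


def extract_window(genome_sequence: str, pam_start: int, strand: str = "+",
                   chrom: str | None = None, site_id: str = "") -> TargetSite:
    """Cut the 60 bp window whose PAM's first base sits at 1-based position 33.

    ``pam_start`` is a 0-based coordinate on the forward strand.  For minus
    strand sites the PAM reads NGG on the reverse complement (CCN forward);
    the forward slice is extracted first and reverse-complemented, so the PAM
    lands at the same window offset in the model's frame.  Missing flank is
    padded with 'N'.
    """
    seq = genome_sequence.upper()
    n = len(seq)
    if not 0 <= pam_start < n:
        raise CoordinateError(f"pam_start {pam_start} outside sequence of length {n}")
    if strand == "+":
        lo, hi = pam_start - LEFT_FLANK, pam_start + RIGHT_FLANK
    elif strand == "-":
        # forward-strand span whose reverse complement has the PAM at offset 32
        lo, hi = pam_start - (RIGHT_FLANK - 1), pam_start + LEFT_FLANK + 1
    else:
        raise InputError(f"strand must be '+' or '-', got {strand!r}")
    core = seq[max(lo, 0): min(hi, n)]
    for i, ch in enumerate(core):
        if ch not in "ACGTN":
            raise EncodingError(
                f"invalid character {ch!r} at source position {max(lo, 0) + i}")
    window = "N" * max(0, -lo) + core + "N" * max(0, hi - n)
    if strand == "-":
        window = reverse_complement(window)
    if not site_id:
        site_id = f"{chrom or 'seq'}:{pam_start}:{strand}"
    return TargetSite(window=window, site_id=site_id, chrom=chrom,
                      pam_start_genomic=pam_start, strand=strand)


def one_hot(window) -> np.ndarray:
    """Encode a 60 bp window as a 4x60 matrix, rows ordered (A, C, G, T).

    A/C/G/T map to unit indicator columns; 'N' maps to the uniform 0.25
    column, so every column sums to 1.
    """
    if isinstance(window, TargetSite):
        window = window.window
    window = window.upper()
    mat = np.zeros((4, len(window)))
    for j, ch in enumerate(window):
        if ch == "N":
            mat[:, j] = 0.25
        elif ch in _ROW:
            mat[_ROW[ch], j] = 1.0
        else:
            raise EncodingError(f"invalid character {ch!r} at window position {j + 1}")
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot` (uniform columns decode to 'N')."""
    out = []
    for col in np.asarray(mat).T:
        if np.allclose(col, 0.25):
            out.append("N")
        else:
            out.append(ALPHABET[int(np.argmax(col))])
    return "".join(out)


def encode_batch(sites) -> np.ndarray:
    """Stack windows into a (n, 4, 60) array."""
    return np.stack([one_hot(s) for s in sites])


def split_dataset(records, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Seeded random partition into train/validation/test.

    Sizes are floors of ``len * ratio``; leftover records go to the first
    (training) part.  Same seed, same partition.
    """
    records = list(records)
    ratios = tuple(float(r) for r in ratios)
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise InputError(f"ratios must be positive and sum to 1, got {ratios}")
    n = len(records)
    if n < len(ratios):
        raise InputError(f"{n} records cannot fill {len(ratios)} parts")
    sizes = [int(np.floor(n * r)) for r in ratios]
    sizes[0] += n - sum(sizes)
    perm = np.random.default_rng(seed).permutation(n)
    parts, start = [], 0
    for s in sizes:
        parts.append([records[i] for i in perm[start: start + s]])
        start += s
    return tuple(parts)


# -- I/O ----------------------------------------------------------------------

SITE_COLUMNS = ["site_id", "chrom", "pam_start", "strand", "window"]


def write_sites_tsv(sites, path) -> None:
    rows = [(s.site_id, s.chrom or ".",
             -1 if s.pam_start_genomic is None else s.pam_start_genomic,
             s.strand, s.window) for s in sites]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[TargetSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    sites = []
    for row in df.itertuples(index=False):
        pam = None if row.pam_start < 0 else int(row.pam_start)
        chrom = None if row.chrom in (".", "nan") else row.chrom
        sites.append(TargetSite(window=row.window, site_id=str(row.site_id),
                                chrom=chrom, pam_start_genomic=pam,
                                strand=row.strand))
    return sites


def read_fasta(path) -> dict[str, str]:
    """Load a (small) FASTA into memory as {name: sequence}."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
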