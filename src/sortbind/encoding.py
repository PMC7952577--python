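"""Sequence + structural-context encoding of binding sites.

Whole-library model inputs are (4+5)x50 binary matrices: a one-hot sequence
block over the 50-nt padded context and a one-hot structural-context block
(LS, B, US, L, N) that is zeroed outside the binding-site span.  Sites are
padded to 50 nt with their true transcript flanks: 10 nt upstream (the last
9 or 8 nt of the ribosomal-initiation region followed by the C or GC prefix
δ) and the 5' end of the mCherry coding sequence downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import CONTEXTS, parse_contexts, UNIFORM_PLACEHOLDER, _rna

#: transcript context flanking the binding site (DNA, as synthesised);
#: the upstream flank ends with the mCherry start codon, the prefix δ sits
#: between that ATG and the site
UPSTREAM_FLANK = "AATTGTGAGCGCTCACAATTATGATAGATTCAATTGGATTAATTAAAGAGGAGAAAGGTACCCATG"
DOWNSTREAM_FLANK = (
    "GTGAGCAAGGGCGAGGAGGATAACATGGCCATCATCAAGGAGTTCATGCGCTTCAAGGTGCACATGGAGGGC"
    "TCCGTGAACGGCCACGAGTTCGAGATCGAGGGCGAGGGCGAGGGCCGCCCCTACGAGGGCACCCAGACCGCC"
    "AAGCTGAAGGTGACCAAGGGTGGCCCCCTGCCCTTCGCCTGGGACATCCTGTCCCCTCAGTTCATGTACGGC"
    "TCCAAGGCCTACGTGAAGCACC"
)

CONTEXT_LENGTH = 50
UPSTREAM_PAD = 10
NUCLEOTIDES = "ACGU"


@dataclass
class EncodedSite:
    """(4+5)x50 one-hot sequence + structure matrix with the site span."""

    matrix: np.ndarray
    site_span: tuple  # half-open column interval occupied by the site
    label: float | None = None

    def __post_init__(self):
        if self.matrix.shape != (9, CONTEXT_LENGTH):
            raise ValueError(f"expected 9x{CONTEXT_LENGTH}, got {self.matrix.shape}")

    @property
    def sequence_block(self) -> np.ndarray:
        return self.matrix[:4]

    @property
    def structure_block(self) -> np.ndarray:
        return self.matrix[4:]


def one_hot(seq: str) -> np.ndarray:
    """4xL one-hot matrix (rows A, C, G, U); T is treated as U and the
    uniform placeholder maps to [0.25]*4."""
    seq = _rna(seq)
    mat = np.zeros((4, len(seq)))
    for col, base in enumerate(seq):
        if base == UNIFORM_PLACEHOLDER:
            mat[:, col] = 0.25
        else:
            try:
                mat[NUCLEOTIDES.index(base), col] = 1.0
            except ValueError:
                raise ValueError(f"invalid nucleotide {base!r} at position {col}")
    return mat


def decode(mat: np.ndarray) -> str:
    """Inverse of one_hot for concrete (non-placeholder) columns."""
    out = []
    for col in mat.T:
        if np.allclose(col, 0.25):
            out.append(UNIFORM_PLACEHOLDER)
        else:
            out.append(NUCLEOTIDES[int(np.argmax(col))])
    return "".join(out)


def pad_to_context(site: str, prefix: str = "C") -> tuple:
    """Pad a binding site to 50 nt with its transcript flanks.

    Returns (padded RNA string, site_span).  The upstream pad is the last
    10-|δ| nt of the initiation-region flank followed by δ (10 nt in total);
    the downstream pad extends the mCherry flank to 50 nt.
    """
    prefix = _rna(prefix)
    if prefix not in ("C", "GC"):
        raise ValueError(f"prefix must be 'C' or 'GC', got {prefix!r}")
    site = _rna(site)
    if len(site) > CONTEXT_LENGTH - UPSTREAM_PAD:
        raise ValueError(f"site longer than {CONTEXT_LENGTH - UPSTREAM_PAD} nt")
    up = _rna(UPSTREAM_FLANK)[-(UPSTREAM_PAD - len(prefix)):] + prefix
    down_len = CONTEXT_LENGTH - UPSTREAM_PAD - len(site)
    down = _rna(DOWNSTREAM_FLANK)[:down_len]
    return up + site + down, (UPSTREAM_PAD, UPSTREAM_PAD + len(site))


def encode(site: str, prefix: str, dotbracket: str, label: float | None = None) -> EncodedSite:
    """Build the 9x50 sequence+structure input for a binding site."""
    if len(dotbracket) != len(site):
        raise ValueError("dot-bracket length does not match the site")
    padded, span = pad_to_context(site, prefix)
    mat = np.zeros((9, CONTEXT_LENGTH))
    mat[:4] = one_hot(padded)
    ann = parse_contexts(dotbracket)  # raises on unbalanced input
    for offset, ctx in enumerate(ann.contexts):
        mat[4 + CONTEXTS.index(ctx), span[0] + offset] = 1.0
    return EncodedSite(mat, span, label)


def encode_dataset(records, fold_backend: str = "builtin") -> tuple:
    """Encode an iterable of (site, prefix, dotbracket, label) rows into a
    stacked (n, 9, 50) tensor and a label vector."""
    sites = [encode(s, p, d, y) for s, p, d, y in records]
    X = np.stack([e.matrix for e in sites])
    y = np.array([e.label for e in sites], dtype=float)
    return X, y
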