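"""De-novo design of non-repetitive binding-site cassettes.

The design space is the Hamming neighbourhood (substitutions only, distance
3-7) of the three wild-type hairpins — about 1.5 billion sequences.  A
balanced sample (equal per-wild-type quotas, so the longer PP7 site does
not dominate) is scored with the three whole-library models; sequences are
classified as single binders (one protein above the 3.5 threshold, the
others below) or dual binders (two above, one below), and cassettes of ten
mutually distant sites are assembled greedily with certified pairwise
distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import edlib
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .scoring import BINDER_THRESHOLD

_NT = "ACGU"
DEFAULT_DMIN, DEFAULT_DMAX = 3, 7
WT_MIN_EDIT = 5                      # distance every design keeps from the WTs
DEFAULT_FORBIDDEN = ("GGATCC", "GTGCAC")   # BamHI / ApaLI, checked on DNA


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b)["editDistance"]


def site_distance(a: str, b: str) -> int:
    """Hamming for equal lengths, edit distance otherwise."""
    return hamming(a, b) if len(a) == len(b) else edit_distance(a, b)


# ---------------------------------------------------------------------------
# neighbourhood counting and sampling
# ---------------------------------------------------------------------------

def count_for_length(length: int, dmin: int = DEFAULT_DMIN,
                     dmax: int = DEFAULT_DMAX) -> int:
    """Closed-form size of the substitution-only Hamming shell: sum over
    k of C(L, k) * 3^k."""
    if dmin > dmax:
        raise ValueError("dmin must not exceed dmax")
    return sum(comb(length, k) * 3 ** k for k in range(dmin, dmax + 1))


def count_variant_space(wts, dmin: int = DEFAULT_DMIN,
                        dmax: int = DEFAULT_DMAX) -> dict:
    """Per-wild-type and total neighbourhood sizes (disjoint by length)."""
    per = {wt.name: count_for_length(len(wt), dmin, dmax) for wt in wts}
    per["total"] = sum(per.values())
    return per


def _mutate_batch(wt_seq: str, ks: np.ndarray, rng) -> list:
    """Vectorised: for each k in ks, substitute k distinct positions of
    wt_seq to distinct alternatives."""
    L = len(wt_seq)
    base_idx = np.frombuffer(wt_seq.translate(
        str.maketrans("ACGU", "\x00\x01\x02\x03")).encode("latin1"), dtype=np.uint8)
    n = len(ks)
    ranks = rng.random((n, L)).argsort(axis=1)
    offs = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
    seqs = np.tile(base_idx, (n, 1))
    kmax = int(ks.max()) if n else 0
    for col in range(kmax):
        rows = ks > col
        pos = ranks[rows, col]
        seqs[np.nonzero(rows)[0], pos] = (seqs[np.nonzero(rows)[0], pos]
                                          + offs[rows, col]) % 4
    lut = np.array(list(_NT), dtype="U1")
    return ["".join(row) for row in lut[seqs]]


def sample_variant_space(wts, n_total: int, seed: int = 0,
                         exclusions=(), dmin: int = DEFAULT_DMIN,
                         dmax: int = DEFAULT_DMAX) -> pd.DataFrame:
    """Balanced random sample of the Hamming neighbourhood.

    Each wild type contributes a quota of floor(n_total / n_wts) unique
    sequences (a 1M request over three wild types gives the printed
    333,333 per part); within a wild type the
    shell k is drawn proportionally to its size C(L,k)*3^k, so sampling is
    uniform over the neighbourhood.  Training-library members and
    ``exclusions`` are rejected.
    """
    wts = list(wts)
    rng = np.random.default_rng(seed)
    exclusions = set(exclusions)
    # the printed per-part quota: floor(n_total / n_wts) from each wild type
    quota = n_total // len(wts)
    frames = []
    for wt in wts:
        want = quota
        space = count_for_length(len(wt), dmin, dmax)
        if want > space - len(exclusions):
            raise ValueError(f"quota {want} exceeds the {wt.name} neighbourhood")
        weights = np.array([comb(len(wt), k) * 3 ** k
                            for k in range(dmin, dmax + 1)], dtype=float)
        weights /= weights.sum()
        seen, out = set(), []
        while len(out) < want:
            batch = max(4096, int((want - len(out)) * 1.2))
            ks = rng.choice(np.arange(dmin, dmax + 1), size=batch, p=weights)
            for seq in _mutate_batch(wt.sequence, ks, rng):
                if seq in seen or seq in exclusions:
                    continue
                seen.add(seq)
                out.append(seq)
                if len(out) == want:
                    break
        frames.append(pd.DataFrame({"sequence": out, "source": wt.name}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# binder classification
# ---------------------------------------------------------------------------

def classify_binders(scores: pd.DataFrame,
                     threshold: float = BINDER_THRESHOLD) -> pd.Series:
    """Label each row of a (sequence x protein) score table.

    single-binder: exactly one protein strictly above the threshold, the
    others strictly below; dual-binder: two above, one below.  Scores
    exactly at the threshold leave the row unclassified.
    """
    above = scores.gt(threshold)
    below = scores.lt(threshold)
    labels = []
    for i in range(len(scores)):
        a = [p for p in scores.columns if above.iloc[i][p]]
        b = [p for p in scores.columns if below.iloc[i][p]]
        if len(a) + len(b) < len(scores.columns):
            labels.append("unclassified")
        elif len(a) == 1:
            labels.append(f"single:{a[0]}")
        elif len(a) == 2:
            labels.append(f"dual:{'+'.join(sorted(a))}")
        elif len(a) == 0:
            labels.append("non-binder")
        else:
            labels.append("multi")
    return pd.Series(labels, index=scores.index, name="label")


# ---------------------------------------------------------------------------
# cassette assembly
# ---------------------------------------------------------------------------

@dataclass
class CassetteSpec:
    """An ordered, certified selection of binding sites for one cassette."""

    sites: list
    scores: pd.DataFrame        # per-site predicted scores, aligned to sites
    intent: str                 # e.g. "single:PCP" or "dual:PCP+QCP"
    min_pairwise: int
    distance_matrix: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.distance_matrix is None:
            n = len(self.sites)
            d = np.zeros((n, n), dtype=int)
            for i in range(n):
                for j in range(i + 1, n):
                    d[i, j] = d[j, i] = site_distance(self.sites[i], self.sites[j])
            self.distance_matrix = d

    def verify(self, wts=()) -> bool:
        """Re-check every pairwise and wild-type distance constraint."""
        n = len(self.sites)
        for i in range(n):
            for j in range(i + 1, n):
                if site_distance(self.sites[i], self.sites[j]) < self.min_pairwise:
                    return False
        for wt in wts:
            for s in self.sites:
                if edit_distance(s, wt.sequence) < WT_MIN_EDIT:
                    return False
        return True


def select_cassette_sites(candidates: pd.DataFrame, intent: str,
                          n_sites: int = 10, min_pairwise: int = 4,
                          wts=(), exclusions=(),
                          forbidden_motifs=DEFAULT_FORBIDDEN) -> CassetteSpec:
    """Greedy cassette selection under distance constraints.

    ``candidates`` holds a ``sequence`` column, one score column per
    protein, and a ``label`` column (from classify_binders).  Candidates
    matching ``intent`` are ranked by descending intended score (the
    minimum over the two proteins for a dual intent), ties broken
    lexicographically, and accepted greedily when at pairwise distance
    >= min_pairwise from every accepted site, edit distance >= 5 from every
    wild type, outside ``exclusions`` and free of the forbidden restriction
    motifs.
    """
    kind, _, targets = intent.partition(":")
    proteins = targets.split("+")
    pool = candidates[candidates["label"] == intent].copy()
    if pool.empty:
        raise ValueError(f"no candidate labelled {intent!r}")
    pool["_rank"] = pool[proteins].min(axis=1)
    pool = pool.sort_values(["_rank", "sequence"], ascending=[False, True])
    exclusions = set(exclusions)
    chosen, rows = [], []
    for _, row in pool.iterrows():
        seq = row["sequence"]
        dna = seq.replace("U", "T")
        if seq in exclusions:
            continue
        if forbidden_motifs and any(m in dna for m in forbidden_motifs):
            continue
        if any(edit_distance(seq, wt.sequence) < WT_MIN_EDIT for wt in wts):
            continue
        if any(site_distance(seq, c) < min_pairwise for c in chosen):
            continue
        chosen.append(seq)
        rows.append(row)
        if len(chosen) == n_sites:
            break
    if len(chosen) < n_sites:
        raise ValueError(
            f"constraints unsatisfiable: only {len(chosen)} of {n_sites} "
            f"sites selectable for {intent!r} at min pairwise {min_pairwise}")
    scores = pd.DataFrame(rows).drop(columns=["_rank"]).reset_index(drop=True)
    return CassetteSpec(chosen, scores, intent, min_pairwise)


def emit_cassette(spec: CassetteSpec, linker: str = "",
                  name: str = "cassette") -> tuple:
    """Concatenate the cassette to a DNA FASTA record plus an annotation
    table of 0-based half-open site intervals."""
    linker_dna = linker.upper().replace("U", "T")
    parts, rows, pos = [], [], 0
    for i, site in enumerate(spec.sites):
        if i > 0:
            parts.append(linker_dna)
            pos += len(linker_dna)
        dna = site.replace("U", "T")
        parts.append(dna)
        rows.append({"site_index": i, "start": pos, "end": pos + len(dna),
                     "sequence": site})
        pos += len(dna)
    full = "".join(parts)
    record = SeqRecord(Seq(full), id=name,
                       description=f"{spec.intent} {len(spec.sites)} sites "
                                   f"min_pairwise={spec.min_pairwise}")
    return record, pd.DataFrame(rows)


def repeated_kmer(seq: str, k: int = 20) -> str | None:
    """First k-mer occurring twice in seq, or None (suffix-scan check that
    the emitted cassette is repeat-free)."""
    seen = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in seen:
            return kmer
        seen[kmer] = i
    return None
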