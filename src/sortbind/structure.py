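"""RNA secondary-structure services for hairpin binding sites.

The binding sites handled here are single hairpins described by five
structural contexts: lower stem (LS), bulge (B), upper stem (US), loop (L)
and no-hairpin (N).  The bulge is the unpaired interior run that splits the
stem into its lower and upper parts; hairpins without a bulge carry a single
stem whose paired positions are all labelled US.

Folding is pluggable: the ``vienna`` backend shells out to ``RNAfold``
(thermodynamic, used for real design runs), while the ``builtin`` backend is
a deterministic Nussinov-style maximum base-pairing fold with minimum loop
length 3 — explicitly non-thermodynamic, intended for tests and environments
without the Vienna package.
"""

from __future__ import annotations

import shutil
import subprocess
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTEXTS = ("LS", "B", "US", "L", "N")
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
#: placeholder for an inserted position encoded as the uniform composition
#: vector [0.25, 0.25, 0.25, 0.25] rather than a concrete base
UNIFORM_PLACEHOLDER = "N"
MIN_LOOP = 3


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

def fold(seq: str, backend: str = "vienna") -> str:
    """Predict the secondary structure of ``seq`` in dot-bracket notation.

    backend="vienna" requires the ``RNAfold`` executable on PATH;
    backend="builtin" runs the bundled maximum base-pairing fold.
    """
    seq = _rna(seq)
    if set(seq) - set("ACGU"):
        raise ValueError(f"non-ACGU characters in sequence: {seq!r}")
    if backend == "vienna":
        return _fold_vienna(seq)
    if backend == "builtin":
        return _fold_nussinov(seq)
    raise ValueError(f"unknown fold backend {backend!r}")


def fold_many(seqs, backend: str = "vienna") -> list:
    """Fold many sequences; the vienna backend runs one RNAfold process."""
    seqs = [_rna(s) for s in seqs]
    if backend != "vienna":
        return [fold(s, backend=backend) for s in seqs]
    if not vienna_available():
        raise RuntimeError("RNAfold not found on PATH; use backend='builtin'")
    out = subprocess.run(
        ["RNAfold", "--noPS"], input="\n".join(seqs) + "\n", text=True,
        capture_output=True, check=True,
    ).stdout.splitlines()
    return [out[2 * i + 1].split()[0] for i in range(len(seqs))]


def vienna_available() -> bool:
    return shutil.which("RNAfold") is not None


def _fold_vienna(seq: str) -> str:
    if not vienna_available():
        raise RuntimeError("RNAfold not found on PATH; use backend='builtin'")
    out = subprocess.run(
        ["RNAfold", "--noPS"], input=seq + "\n", text=True,
        capture_output=True, check=True,
    ).stdout.splitlines()
    return out[1].split()[0]


def _fold_nussinov(seq: str) -> str:
    """Maximum base-pairing fold (canonical + wobble pairs, min loop 3).

    Deterministic: ties are broken by preferring i unpaired, then the
    smallest pairing partner index.
    """
    n = len(seq)
    dp = np.zeros((n + 1, n + 1), dtype=int)  # dp[i][j]: max pairs in seq[i:j]
    for span in range(MIN_LOOP + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + MIN_LOOP + 1, j):
                if (seq[i], seq[k]) in _PAIRS:
                    cand = 1 + dp[i + 1][k] + dp[k + 1][j]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    struct = ["."] * n

    def trace(i: int, j: int) -> None:
        if j - i < MIN_LOOP + 2:
            return
        if dp[i][j] == dp[i + 1][j]:
            trace(i + 1, j)
            return
        for k in range(i + MIN_LOOP + 1, j):
            if (seq[i], seq[k]) in _PAIRS and dp[i][j] == 1 + dp[i + 1][k] + dp[k + 1][j]:
                struct[i], struct[k] = "(", ")"
                trace(i + 1, k)
                trace(k + 1, j)
                return

    trace(0, n)
    return "".join(struct)


# ---------------------------------------------------------------------------
# context parsing
# ---------------------------------------------------------------------------

@dataclass
class HairpinAnnotation:
    """Per-position structural contexts and base-pair partners of a hairpin."""

    contexts: list
    partner: list  # partner index or None

    def runs(self) -> list:
        """Maximal runs of equal context as (context, length) pairs."""
        out = []
        for c in self.contexts:
            if out and out[-1][0] == c:
                out[-1][1] += 1
            else:
                out.append([c, 1])
        return [(c, n) for c, n in out]

    def positions(self, context: str) -> list:
        return [i for i, c in enumerate(self.contexts) if c == context]

    def pairs(self) -> list:
        """Base pairs as (i, j) with i < j, outermost first."""
        return sorted((i, j) for i, j in enumerate(self.partner)
                      if j is not None and i < j)


def pair_table(dotbracket: str) -> list:
    """Partner index per position (None if unpaired); raises on imbalance."""
    partner = [None] * len(dotbracket)
    stack = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket: unmatched ')'")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r}")
    if stack:
        raise ValueError("unbalanced dot-bracket: unmatched '('")
    return partner


def _hairpin_loops(dotbracket: str, partner: list) -> int:
    """Number of hairpin loops (pairs that enclose no other pair)."""
    n = 0
    for i, j in ((i, j) for i, j in enumerate(partner) if j is not None and i < j):
        if all(partner[k] is None for k in range(i + 1, j)):
            n += 1
    return n


def parse_contexts(dotbracket: str) -> HairpinAnnotation:
    """Assign LS/B/US/L/N contexts to every position of a single hairpin.

    Loop: the unpaired run enclosed by the innermost pair.  Interior unpaired
    runs between stem segments (either strand side) are bulges.  Paired
    positions whose pair interval encloses a bulge position are lower stem,
    the rest upper stem; bulge-free hairpins therefore carry a single all-US
    stem.  Exterior unpaired positions are N.  Strings containing more than
    one hairpin are annotated all-N with a warning.
    """
    partner = pair_table(dotbracket)
    n = len(dotbracket)
    if all(p is None for p in partner):
        return HairpinAnnotation(["N"] * n, partner)
    if _hairpin_loops(dotbracket, partner) > 1:
        warnings.warn("multi-hairpin structure; annotating all positions as N")
        return HairpinAnnotation(["N"] * n, [None] * n)

    contexts = [None] * n
    # innermost pair encloses the loop
    inner_i, inner_j = max(
        ((i, j) for i, j in enumerate(partner) if j is not None and i < j),
        key=lambda ij: ij[0],
    )
    for k in range(inner_i + 1, inner_j):
        contexts[k] = "L"
    outer_i = min(i for i, j in enumerate(partner) if j is not None)
    outer_j = partner[outer_i]
    for k in range(n):
        if contexts[k] is None and partner[k] is None:
            contexts[k] = "B" if outer_i < k < outer_j else "N"
    bulges = [k for k in range(n) if contexts[k] == "B"]
    for i, j in ((i, j) for i, j in enumerate(partner) if j is not None and i < j):
        encloses_bulge = any(i < b < j for b in bulges)
        contexts[i] = contexts[j] = "LS" if encloses_bulge else "US"
    return HairpinAnnotation(contexts, partner)


# ---------------------------------------------------------------------------
# structure-altering mutagenesis
# ---------------------------------------------------------------------------

@dataclass
class MutSpec:
    """A structure edit: upper-stem/loop length change or bulge resizing.

    kind: "stem" or "loop" with magnitude in {-2,-1,+1,+2}, or "bulge" with
    target size in {0, 2}.  Inserted positions are encoded as the uniform
    composition vector (placeholder base), never a concrete nucleotide, so
    structural effects stay decoupled from sequence effects.
    """

    kind: str
    magnitude: int

    def __post_init__(self):
        if self.kind in ("stem", "loop"):
            if self.magnitude not in (-2, -1, 1, 2):
                raise ValueError("stem/loop magnitude must be in {-2,-1,1,2}")
        elif self.kind == "bulge":
            if self.magnitude not in (0, 2):
                raise ValueError("bulge target size must be 0 or 2")
        else:
            raise ValueError(f"unknown mutation kind {self.kind!r}")


@dataclass
class StructuredSite:
    """A binding site with its dot-bracket; sequence may contain the
    uniform placeholder for structurally inserted positions."""

    sequence: str
    dotbracket: str
    flags: list = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence and dot-bracket lengths differ")

    @property
    def annotation(self) -> HairpinAnnotation:
        return parse_contexts(self.dotbracket)


def _insert(site: StructuredSite, idx: int, base: str, sym: str) -> StructuredSite:
    s, d = site.sequence, site.dotbracket
    return StructuredSite(s[:idx] + base + s[idx:], d[:idx] + sym + d[idx:],
                          list(site.flags))


def _delete(site: StructuredSite, idxs) -> StructuredSite:
    keep = [k for k in range(len(site.sequence)) if k not in set(idxs)]
    return StructuredSite("".join(site.sequence[k] for k in keep),
                          "".join(site.dotbracket[k] for k in keep),
                          list(site.flags))


def mutate_structure(site: StructuredSite, spec: MutSpec, seed: int) -> StructuredSite:
    """Apply one structure edit, re-annotate, and flag degenerate outcomes."""
    rng = np.random.default_rng(seed)
    ann = site.annotation
    before = {c for c, _ in ann.runs()}
    out = site

    if spec.kind == "stem":
        us_pairs = [(i, j) for i, j in ann.pairs()
                    if ann.contexts[i] == "US"]
        if spec.magnitude > 0:
            for _ in range(spec.magnitude):
                ann_now = out.annotation
                cand = [(i, j) for i, j in ann_now.pairs() if ann_now.contexts[i] == "US"]
                if not cand:
                    cand = ann_now.pairs()
                i, j = cand[rng.integers(len(cand))]
                # insert the new pair just inside the chosen pair
                out = _insert(out, j, UNIFORM_PLACEHOLDER, ")")
                out = _insert(out, i + 1, UNIFORM_PLACEHOLDER, "(")
        else:
            ndel = -spec.magnitude
            if ndel > len(us_pairs):
                raise ValueError("deletion larger than the upper-stem run")
            chosen = rng.choice(len(us_pairs), size=ndel, replace=False)
            idxs = [k for c in chosen for k in us_pairs[c]]
            out = _delete(out, idxs)
    elif spec.kind == "loop":
        loop = ann.positions("L")
        if spec.magnitude > 0:
            for _ in range(spec.magnitude):
                pos = out.annotation.positions("L")
                out = _insert(out, pos[rng.integers(len(pos))], UNIFORM_PLACEHOLDER, ".")
        else:
            ndel = -spec.magnitude
            if ndel > len(loop):
                raise ValueError("deletion larger than the loop run")
            idxs = rng.choice(loop, size=ndel, replace=False)
            out = _delete(out, idxs)
            if len(loop) - ndel < MIN_LOOP:
                out.flags.append("loop_below_minimum")
    else:  # bulge
        bulge = ann.positions("B")
        target = spec.magnitude
        if target > len(bulge):
            if bulge:
                anchor = bulge[0]
            else:
                # create a bulge between two adjacent 5'-side stem pairs
                open_idx = [i for i, j in ann.pairs()]
                if len(open_idx) < 2:
                    raise ValueError("no stem to split with a bulge")
                anchor = open_idx[len(open_idx) // 2]
            for _ in range(target - len(bulge)):
                out = _insert(out, anchor + 1, UNIFORM_PLACEHOLDER, ".")
        elif target < len(bulge):
            idxs = rng.choice(bulge, size=len(bulge) - target, replace=False)
            out = _delete(out, idxs)

    after = {c for c, _ in out.annotation.runs()}
    if "US" in before and "US" not in after:
        out.flags.append("upper_stem_lost")
    if "B" in before and "B" not in after and spec.kind != "bulge":
        out.flags.append("bulge_merged")
    if out.dotbracket.count("(") != out.dotbracket.count(")"):
        raise AssertionError("pairedness bookkeeping violated")
    return out


def instantiate(site: StructuredSite, seed: int) -> str:
    """Replace uniform-placeholder positions by concrete bases.

    Paired placeholders are drawn jointly as A-U or C-G; unpaired ones
    uniformly over ACGU.  The seed is the caller's responsibility to log.
    """
    rng = np.random.default_rng(seed)
    seq = list(site.sequence)
    partner = pair_table(site.dotbracket)
    for i, b in enumerate(seq):
        if b != UNIFORM_PLACEHOLDER:
            continue
        j = partner[i]
        if j is not None and i < j:
            x = ("A", "C")[rng.integers(2)]
            seq[i], seq[j] = x, _WC[x]
        elif j is None:
            seq[i] = "ACGU"[rng.integers(4)]
    return "".join(seq)


def refold_matches(site: StructuredSite, seed: int, backend: str = "vienna") -> bool:
    """Post-check hook: re-fold a concrete instantiation and compare the
    structural-context run profile with the intended one."""
    seq = instantiate(site, seed)
    refolded = fold(seq, backend=backend)
    return parse_contexts(refolded).runs() == site.annotation.runs()


# ---------------------------------------------------------------------------
# SNP / DNP maps
# ---------------------------------------------------------------------------

def snp_dnp_scan(wt, model) -> pd.DataFrame:
    """Predicted responsiveness change for every structure-compatible point
    mutation of a wild-type hairpin.

    Loop and bulge positions receive all three single-nucleotide
    substitutions (SNP); each stem pair receives the three joint
    complementary pair swaps (DNP) so stem structure is preserved.  ``model``
    is either a callable ``f(sequence, dotbracket) -> score`` or an object
    with that interface under ``predict_site``.
    """
    predict = model if callable(model) else model.predict_site
    seq = _rna(wt.sequence)
    ann = parse_contexts(wt.dotbracket)
    base = predict(seq, wt.dotbracket)
    rows = []
    for i in ann.positions("L") + ann.positions("B"):
        for alt in (b for b in "ACGU" if b != seq[i]):
            mut = seq[:i] + alt + seq[i + 1:]
            rows.append({"position": i, "kind": "SNP", "partner": None,
                         "alternative": alt,
                         "delta": predict(mut, wt.dotbracket) - base})
    for i, j in ann.pairs():
        for alt in (b for b in "ACGU" if b != seq[i]):
            mut = list(seq)
            mut[i], mut[j] = alt, _WC[alt]
            rows.append({"position": i, "kind": "DNP", "partner": j,
                         "alternative": f"{alt}-{_WC[alt]}",
                         "delta": predict("".join(mut), wt.dotbracket) - base})
    return pd.DataFrame(rows)
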