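"""Synthetic oligo libraries and simulated induction Sort-seq experiments.

The simulator emulates the experiment end to end with known ground truth:
a barcoded oligo library of wild-type-derived binding-site variants (three
sub-libraries with positive and negative controls), dose-dependent
repression of the mCherry reporter for true binders, per-inducer-level
multiplicative "day-effect" fluorescence distortions, log-normal single-cell
noise, FACS binning over eight log-spaced fluorescence gates, and
per-(level, bin) multinomial read sampling at equal per-bin sequencing
depth.  Every downstream stage of the package can therefore be tested as a
parameter-recovery problem.

Defaults describe the emulated study conditions: six inducer concentrations
(0 to 200 uM in decades), eight bins spanning the library fluorescence
range except the top 5%, day-effect multipliers grouping levels 1/4/6,
Hill repression with coefficient 1, and moderate binder affinities so the
repressed dose-response stays inside the sorter range.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .quantify import ReadCountTensor, N_LEVELS, N_BINS
from .sites import WildTypeSite
from .structure import parse_contexts, _WC

_NT = "ACGU"
#: suffix that restores the reading frame for a given (prefix+site) length
_FRAME_SUFFIX = {0: "", 1: "U", 2: "CU"}


@dataclass(frozen=True)
class VariantRecord:
    """One barcoded oligo-library entry with synthetic ground truth."""

    variant_id: str
    design_id: str          # shared by the <=5 barcodes of one configuration
    site_sequence: str
    prefix: str             # delta in {C, GC}
    suffix: str
    barcode_index: int
    barcode: str
    origin: str             # WT name or "control"
    control: str            # {positive, negative, none}
    truth_kd: float         # inf for non-binders (synthetic ground truth)
    truth_basal: float

    def __post_init__(self):
        if (len(self.prefix) + len(self.site_sequence) + len(self.suffix)) % 3 != 0:
            raise ValueError("prefix+site+suffix must preserve the reading frame")
        if not 1 <= self.barcode_index <= 5:
            raise ValueError("at most 5 barcodes per variant")
        if self.control not in ("positive", "negative", "none"):
            raise ValueError(f"bad control label {self.control!r}")


@dataclass
class SimConfig:
    """Study conditions for one simulated Sort-seq run."""

    inducer_levels: tuple = (0.0, 0.02, 0.2, 2.0, 20.0, 200.0)
    bin_count: int = N_BINS
    fluor_range: tuple = (1e2, 3e4)
    reads_per_level: int = 4_000_000
    day_effect: tuple = (0.5, 1.0, 1.0, 0.5, 1.0, 0.5)
    hill_coefficient: float = 1.0
    noise_cv: float = 0.3
    background_fraction: float = 0.05
    seed: int = 0
    bin_edges: np.ndarray = field(default=None)

    def __post_init__(self):
        if len(self.inducer_levels) != N_LEVELS or len(self.day_effect) != N_LEVELS:
            raise ValueError("six inducer levels and day-effect multipliers required")
        if not all(d > 0 for d in self.day_effect):
            raise ValueError("day_effect multipliers must be positive")
        if self.bin_edges is None:
            # log-spaced upper boundaries spanning the fluorescence range
            # except the top 5% (in log space)
            lo, hi = self.fluor_range
            top = np.exp(np.log(lo) + 0.95 * (np.log(hi) - np.log(lo)))
            edges = np.geomspace(lo, top, self.bin_count + 1)[1:]
            self.bin_edges = np.tile(edges, (N_LEVELS, 1))
        else:
            self.bin_edges = np.asarray(self.bin_edges, dtype=float)
            if self.bin_edges.ndim == 1:
                self.bin_edges = np.tile(self.bin_edges, (N_LEVELS, 1))
        if not (np.diff(self.bin_edges, axis=1) > 0).all():
            raise ValueError("bin_edges must be strictly increasing")


# ---------------------------------------------------------------------------
# library design
# ---------------------------------------------------------------------------

def _preserving_mutant(wt: WildTypeSite, n_edits: int, rng) -> str:
    """Structure-preserving mutant: compensatory stem pair swaps and
    loop/bulge point substitutions."""
    seq = list(wt.sequence)
    ann = wt.annotation
    pairs = ann.pairs()
    unpaired = ann.positions("L") + ann.positions("B")
    for _ in range(n_edits):
        if pairs and (not unpaired or rng.random() < 0.5):
            i, j = pairs[rng.integers(len(pairs))]
            x = _NT[rng.integers(4)]
            seq[i], seq[j] = x, _WC[x]
        else:
            i = unpaired[rng.integers(len(unpaired))]
            seq[i] = _NT[rng.integers(4)]
    return "".join(seq)


def _altering_mutant(wt: WildTypeSite, n_subs: int, indel_prob: float, rng) -> str:
    """Structure-altering mutant: random substitutions, sometimes an indel."""
    seq = list(wt.sequence)
    pos = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    for i in pos:
        alts = [b for b in _NT if b != seq[i]]
        seq[i] = alts[rng.integers(3)]
    if rng.random() < indel_prob:
        if rng.random() < 0.5 and len(seq) > 10:
            del seq[rng.integers(len(seq))]
        else:
            seq.insert(rng.integers(len(seq) + 1), _NT[rng.integers(4)])
    return "".join(seq)


def _random_hairpinless(length: int, rng) -> str:
    return "".join(_NT[b] for b in rng.integers(4, size=length))


def _frame_suffix(prefix: str, site: str) -> str:
    return _FRAME_SUFFIX[(-len(prefix) - len(site)) % 3]


def _barcode(rng, length: int = 12) -> str:
    return "".join("ACGT"[b] for b in rng.integers(4, size=length))


def design_library(wts, n_sites: int = 10_000, control_counts=(75, 187),
                   seed: int = 0, n_barcodes: int = 5, prefixes=("C", "GC"),
                   max_hamming: int = 7, preserve_edits=(1, 3),
                   alter_edits=(1, 7), indel_prob: float = 0.3,
                   kd_wt: float = 100.0, kd_range=(60.0, 600.0),
                   basal_range=(3e3, 8e3)) -> list:
    """Design a barcoded variant library with known ground-truth affinities.

    ``n_sites`` mutated sites are split round-robin over the wild types,
    half structure-preserving (finite ground-truth Kd: binders) and half
    structure-altering (Kd = inf: non-binders).  Every configuration is
    emitted at both prefixes and ``n_barcodes`` barcodes.  Positive controls
    are wild-type copies; negative controls are random non-hairpin
    sequences.  ``preserve_edits``/``alter_edits`` of (0, 0) yield wild-type
    copies (identity degenerate case).
    """
    wts = list(wts)
    if not wts:
        raise ValueError("at least one wild-type site required")
    if n_sites < 1:
        raise ValueError("n_sites must be at least 1")
    if len({w.name for w in wts}) != len(wts):
        raise ValueError("duplicate wild-type names")
    rng = np.random.default_rng(seed)
    barcodes_seen = set()

    def fresh_barcode():
        while True:
            b = _barcode(rng)
            if b not in barcodes_seen:
                barcodes_seen.add(b)
                return b

    records = []

    def emit(tag, site, origin, control, kd, basal):
        for prefix in prefixes:
            design = f"{tag}_d{prefix}"
            for b in range(1, n_barcodes + 1):
                records.append(VariantRecord(
                    variant_id=f"{design}_b{b}", design_id=design,
                    site_sequence=site, prefix=prefix.replace("T", "U"),
                    suffix=_frame_suffix(prefix, site), barcode_index=b,
                    barcode=fresh_barcode(), origin=origin, control=control,
                    truth_kd=kd, truth_basal=basal))

    def basal():
        lo, hi = basal_range
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    for m in range(n_sites):
        wt = wts[m % len(wts)]
        preserving = (m // len(wts)) % 2 == 0
        if preserving:
            n_edits = int(rng.integers(preserve_edits[0], preserve_edits[1] + 1))
            site = _preserving_mutant(wt, n_edits, rng)
            lo, hi = kd_range
            kd = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            n_subs = int(rng.integers(alter_edits[0],
                                      min(alter_edits[1], max_hamming) + 1))
            site = _altering_mutant(wt, n_subs, indel_prob, rng)
            kd = np.inf
        emit(f"{wt.name}_m{m:05d}", site, wt.name, "none", kd, basal())

    n_pos, n_neg = control_counts
    for c in range(n_pos):
        wt = wts[c % len(wts)]
        emit(f"pos{c:04d}_{wt.name}", wt.sequence, wt.name, "positive",
             kd_wt, basal())
    for c in range(n_neg):
        length = int(rng.integers(19, 26))
        emit(f"neg{c:04d}", _random_hairpinless(length, rng), "control",
             "negative", np.inf, basal())
    return records


def library_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# oligo assembly
# ---------------------------------------------------------------------------

DEFAULT_PARTS = {
    "restriction5": "GGATCC",                       # BamHI
    "promoter": "TTGACAGCTAGCTCAGTCCTAGGTATAATGCTAGC",
    "rbs": "AAAGAGGAGAAA",
    "start": "ATG",
    "mcherry": ("GTGAGCAAGGGCGAGGAGGATAACATGGCCATCATCAAGGAGTTCATGCGCTTCAAGGTG"
                "CACATGGAGGGCTCCGTGAACGGCCACGAGTTCGAGATCGAGGGCGAGGGCGAGGGCCGC"
                "CCCTACGAGGGCACC"),
    "restriction3": "GTGCAC",                       # ApaLI
    "oligo_length": 210,
}


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def assemble_oligo(v: VariantRecord, parts: dict | None = None) -> str:
    """Concatenate the oligo components in synthesis order, padding or
    trimming the mCherry 5' segment to the configured total length."""
    p = dict(DEFAULT_PARTS, **(parts or {}))
    if not v.barcode:
        raise ValueError("empty barcode")
    head = [p["restriction5"], v.barcode, p["promoter"], p["rbs"], p["start"],
            _dna(v.prefix), _dna(v.site_sequence)]
    for comp in head + [p["mcherry"], p["restriction3"]]:
        if set(comp) - set("ACGT"):
            raise ValueError(f"non-ACGT characters in component {comp!r}")
    fixed = sum(map(len, head)) + len(p["restriction3"])
    room = p["oligo_length"] - fixed
    if room < 0:
        raise ValueError("components exceed the configured oligo length")
    mch = (p["mcherry"] + p["mcherry"])[:room] if room > len(p["mcherry"]) \
        else p["mcherry"][:room]
    return "".join(head) + mch + p["restriction3"]


def parse_oligo(oligo: str, v: VariantRecord, parts: dict | None = None) -> dict:
    """Split an assembled oligo back into its components (known lengths)."""
    p = dict(DEFAULT_PARTS, **(parts or {}))
    lens = [len(p["restriction5"]), len(v.barcode), len(p["promoter"]),
            len(p["rbs"]), len(p["start"]), len(v.prefix),
            len(v.site_sequence)]
    names = ["restriction5", "barcode", "promoter", "rbs", "start", "prefix",
             "site"]
    out, pos = {}, 0
    for name, ln in zip(names, lens):
        out[name] = oligo[pos:pos + ln]
        pos += ln
    out["mcherry"] = oligo[pos:-len(p["restriction3"])]
    out["restriction3"] = oligo[-len(p["restriction3"]):]
    return out


# ---------------------------------------------------------------------------
# dose response and sorting
# ---------------------------------------------------------------------------

def simulate_dose_response(v: VariantRecord, cfg: SimConfig) -> np.ndarray:
    """Mean reporter fluorescence across the six inducer levels.

    Hill repression with protein level proportional to inducer
    concentration: mean_j = basal / (1 + (c_j / Kd)^h).  Non-binders
    (Kd = inf) give a flat vector at the basal level.
    """
    if not v.truth_kd > 0:
        raise ValueError("truth_kd must be positive")
    c = np.asarray(cfg.inducer_levels, dtype=float)
    if np.isinf(v.truth_kd):
        return np.full(N_LEVELS, float(v.truth_basal))
    return v.truth_basal / (1.0 + (c / v.truth_kd) ** cfg.hill_coefficient)


def dose_response_table(records, cfg: SimConfig) -> pd.DataFrame:
    """Per-variant 6-level mean fluorescence for a list of records."""
    return pd.DataFrame(
        {r.variant_id: simulate_dose_response(r, cfg) for r in records},
        index=range(1, N_LEVELS + 1)).T


def _bin_probabilities(medians: np.ndarray, edges: np.ndarray, cv: float,
                       background: float = 0.0,
                       fluor_range: tuple | None = None) -> np.ndarray:
    """P(cell of median m falls in bin k) for log-normal single-cell noise.

    The log-normal is anchored at the median; bin k covers
    (edge_{k-1}, edge_k] with edge_0 = 0, and fluorescence above the top
    edge (the excluded top 5% of the range) is lost.  A small ``background``
    fraction of events is spread log-uniformly over the sorter range,
    emulating debris/doublet/maturation events whose fluorescence is
    uncorrelated with the variant; this is what populates distant gates
    for every variant.
    """
    sigma = np.sqrt(np.log(1.0 + cv ** 2)) if cv > 0 else 1e-9
    z = (np.log(edges)[None, :] - np.log(medians)[:, None]) / sigma
    cdf = norm.cdf(z)
    probs = np.diff(np.concatenate([np.zeros((len(medians), 1)), cdf], axis=1))
    if background > 0:
        lo, hi = fluor_range if fluor_range is not None else (edges[0], edges[-1])
        span = np.log(hi) - np.log(lo)
        cum_bg = np.clip((np.log(edges) - np.log(lo)) / span, 0.0, 1.0)
        bg = np.diff(np.concatenate([[0.0], cum_bg]))
        probs = (1.0 - background) * probs + background * bg[None, :]
    return probs


def simulate_sortseq(means: pd.DataFrame, cfg: SimConfig,
                     abundance=None) -> ReadCountTensor:
    """Sort a library of dose-responses into the 6x8 read-count tensor.

    For each inducer level, single-cell fluorescences follow a log-normal
    around day_effect(j) x mean(i, j); cells are gated into the eight bins
    and each (level, bin) is sequenced to equal depth reads_per_level / 8,
    reads drawn multinomially across variants in proportion to their cell
    counts in that bin.  The true per-(level, bin) cell fractions are
    recorded so Eq-style read normalisation can undo the binning geometry.
    """
    if cfg.reads_per_level < 1:
        raise ValueError("sequencing depth must be positive")
    rng = np.random.default_rng(cfg.seed)
    ids = list(means.index)
    m = means.to_numpy(dtype=float)
    if abundance is None:
        abundance = np.full(len(ids), 1.0 / len(ids))
    abundance = np.asarray(abundance, dtype=float)
    counts = np.zeros((len(ids), N_LEVELS, N_BINS), dtype=int)
    cells = np.zeros((N_LEVELS, N_BINS))
    depth = cfg.reads_per_level // N_BINS
    for j in range(N_LEVELS):
        probs = _bin_probabilities(cfg.day_effect[j] * m[:, j],
                                   cfg.bin_edges[j], cfg.noise_cv,
                                   background=cfg.background_fraction,
                                   fluor_range=cfg.fluor_range)
        occupancy = abundance[:, None] * probs          # cells per (variant, bin)
        cells[j] = occupancy.sum(axis=0)
        for k in range(N_BINS):
            tot = occupancy[:, k].sum()
            if tot <= 0:
                continue
            counts[:, j, k] = rng.multinomial(depth, occupancy[:, k] / tot)
    return ReadCountTensor(ids, counts, cells, cfg.bin_edges.copy())


# ---------------------------------------------------------------------------
# FASTQ emission
# ---------------------------------------------------------------------------

def make_level_bin_barcodes() -> dict:
    """Deterministic 8-nt barcodes for the 48 (level, bin) sorting gates."""
    kmers = ("".join(p) for p in itertools.product("ACGT", repeat=4))
    table = {}
    for (j, k), kmer in zip(itertools.product(range(1, N_LEVELS + 1),
                                              range(1, N_BINS + 1)), kmers):
        table[kmer + kmer[::-1]] = (j, k)
    return table


def write_fastq(t: ReadCountTensor, records, handle,
                level_bin_barcodes: dict | None = None, stub: str = "ACGT" * 5):
    """Write the tensor out as 4-line Phred33 FASTQ reads: bin/level barcode
    + variant barcode + constant stub, constant quality."""
    if level_bin_barcodes is None:
        level_bin_barcodes = make_level_bin_barcodes()
    bc_of = {r.variant_id: r.barcode for r in records}
    inv = {jk: bc for bc, jk in level_bin_barcodes.items()}
    n = 0
    for i, vid in enumerate(t.variant_ids):
        for j in range(N_LEVELS):
            for k in range(N_BINS):
                seq = inv[(j + 1, k + 1)] + bc_of[vid] + stub
                for _ in range(int(t.counts[i, j, k])):
                    handle.write(f"@read{n}\n{seq}\n+\n{'I' * len(seq)}\n")
                    n += 1
    return n
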