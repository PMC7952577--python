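"""Wild-type binding-site records for the three phage coat proteins.

The default sites — the canonical PP7, MS2 and Qβ hairpins (25, 19 and
20 nt) — ship as editable FASTA plus dot-bracket annotation files under
``sortbind/data``; the dot-brackets were produced by RNAfold and all three
form a single hairpin with a one-nucleotide 5'-side bulge.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio import SeqIO

from .structure import pair_table, parse_contexts, _hairpin_loops, _rna


@dataclass(frozen=True)
class WildTypeSite:
    """A wild-type coat-protein binding hairpin.

    name associates the site with its protein (PP7→PCP, MS2→MCP, Qbeta→QCP).
    """

    name: str
    sequence: str
    dotbracket: str

    def __post_init__(self):
        seq = _rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if len(seq) != len(self.dotbracket):
            raise ValueError(f"{self.name}: sequence/dot-bracket length mismatch")
        partner = pair_table(self.dotbracket)  # raises if unbalanced
        if _hairpin_loops(self.dotbracket, partner) != 1:
            raise ValueError(f"{self.name}: annotation is not a single hairpin")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def annotation(self):
        return parse_contexts(self.dotbracket)


#: protein label associated with each default wild type
PROTEIN_OF = {"PP7": "PCP", "MS2": "MCP", "Qbeta": "QCP"}


def load_default_wildtypes() -> list:
    """The three canonical wild-type hairpins bundled with the package."""
    data = resources.files("sortbind.data")
    seqs = {}
    with (data / "wt_sites.fasta").open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seqs[rec.id] = str(rec.seq)
    wts = []
    for line in (data / "wt_sites.dbn").read_text().splitlines():
        name, dbn = line.split("\t")
        wts.append(WildTypeSite(name, seqs[name], dbn))
    return wts
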