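"""Splice-variant sequences of α-synuclein and sequence-derived properties.

The SNCA gene carries two cassette exons that can be skipped during
splicing: exon 3 encodes residues 41–54 of the canonical 140-residue
protein, and exon 5 encodes residues 103–130.  Skipping one or both
yields the isoforms αSynΔ3 (126 aa), αSynΔ5 (112 aa) and αSynΔ3Δ5
(98 aa).  This module builds those variants on the canonical frame,
keeps a per-residue map back to canonical numbering, and computes the
simple sequence bookkeeping used downstream: charged-residue counts,
A280 extinction coefficients, and the set of canonical residue pairs
shared by a group of variants (with pairs that straddle a spliced-out
region masked).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical human α-synuclein (140 residues).
CANONICAL_SEQUENCE = (
    "MDVFMKGLSKAKEGVVAAAEKTKQGVAEAAGKTKEGVLYV"
    "GSKTKEGVVHGVATVAEKTKEQVTNVGGAVVTGVTAVAQK"
    "TVEGAGSIAAATGFVKKDQLGKNEEGAPQEGILEDMPVDP"
    "DNEAYEMPSEEGYQDYEPEA"
)

#: Canonical residue spans (1-based, inclusive) encoded by the cassette exons.
EXON3_SPAN = (41, 54)
EXON5_SPAN = (103, 130)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

# Pace extinction coefficients at 280 nm (M^-1 cm^-1).
_EPS_TYR = 1490
_EPS_TRP = 5500
_EPS_CYSTINE = 125


@dataclass(frozen=True)
class SpliceVariant:
    """A splice variant with a map back to canonical residue numbering.

    ``canonical_index[k]`` is the canonical (1-based) position of residue
    ``k`` (0-based) of ``sequence``; it is strictly increasing.
    """

    name: str
    sequence: str
    exon3_present: bool
    exon5_present: bool
    canonical_index: tuple[int, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.canonical_index):
            raise ValueError("sequence and canonical_index lengths differ")
        if any(b <= a for a, b in itertools.pairwise(self.canonical_index)):
            raise ValueError("canonical_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceProperties:
    n_negative: int
    n_positive: int
    n_his: int
    net_charge_formal: int
    epsilon_280: int


def build_variant(exon3: bool, exon5: bool, name: str | None = None) -> SpliceVariant:
    """Build a splice variant from the canonical frame.

    Parameters
    ----------
    exon3, exon5
        Whether the corresponding cassette exon is retained.
    name
        Optional label; defaults to FL / d3 / d5 / d3d5.
    """
    removed: set[int] = set()
    if not exon3:
        removed.update(range(EXON3_SPAN[0], EXON3_SPAN[1] + 1))
    if not exon5:
        removed.update(range(EXON5_SPAN[0], EXON5_SPAN[1] + 1))
    idx = tuple(i for i in range(1, len(CANONICAL_SEQUENCE) + 1) if i not in removed)
    seq = "".join(CANONICAL_SEQUENCE[i - 1] for i in idx)
    if name is None:
        name = {(True, True): "FL", (False, True): "d3",
                (True, False): "d5", (False, False): "d3d5"}[(exon3, exon5)]
    return SpliceVariant(name, seq, exon3, exon5, idx)


def splice_isoforms() -> dict[str, SpliceVariant]:
    """The four isoforms studied experimentally, keyed by label."""
    return {
        "FL": build_variant(True, True),
        "d3": build_variant(False, True),
        "d5": build_variant(True, False),
        "d3d5": build_variant(False, False),
    }


def sequence_properties(seq: str) -> SequenceProperties:
    """Charge counts and the Pace A280 extinction coefficient.

    His is counted separately from the formal positives (its charge at
    neutral pH is fractional; a pH-dependent charge is available in the
    coarse-grained module).  αSyn has no Cys, so the cystine term is zero
    unless the sequence contains pairs of cysteines, all of which are
    conservatively assumed oxidised.
    """
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-canonical residue letters: {sorted(bad)}")
    n_neg = sum(seq.count(a) for a in "DE")
    n_pos = sum(seq.count(a) for a in "KR")
    n_his = seq.count("H")
    eps = (_EPS_TYR * seq.count("Y") + _EPS_TRP * seq.count("W")
           + _EPS_CYSTINE * (seq.count("C") // 2))
    return SequenceProperties(n_neg, n_pos, n_his, n_pos - n_neg, eps)


def _common_blocks(variants: Iterable[SpliceVariant]) -> list[range]:
    """Contiguous runs of canonical positions present in every variant."""
    sets = [set(v.canonical_index) for v in variants]
    if not sets:
        raise ValueError("need at least one variant")
    common = sorted(set.intersection(*sets))
    blocks: list[range] = []
    start = prev = None
    for i in common:
        if start is None:
            start = prev = i
        elif i == prev + 1:
            prev = i
        else:
            blocks.append(range(start, prev + 1))
            start = prev = i
    if start is not None:
        blocks.append(range(start, prev + 1))
    return blocks


def common_pair_mask(variants: Iterable[SpliceVariant]) -> set[tuple[int, int]]:
    """Unordered canonical residue pairs shared by all variants.

    A pair is kept only if both members fall in the same contiguous block
    of common residues: pairs crossing a potentially spliced-out region
    are masked because their distance is not comparable across variants.
    For the four αSyn isoforms the blocks are 1–40, 55–102 and 131–140,
    giving C(40,2) + C(48,2) + C(10,2) = 1953 pairs.
    """
    variants = list(variants)
    if not variants:
        raise ValueError("empty variant set")
    pairs: set[tuple[int, int]] = set()
    for block in _common_blocks(variants):
        pairs.update(itertools.combinations(block, 2))
    return pairs


# ---------------------------------------------------------------- I/O


def write_fasta(variants: Iterable[SpliceVariant], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(v.sequence), id=v.name,
                  description=f"exon3={v.exon3_present} exon5={v.exon5_present}")
        for v in variants
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read plain sequences; canonical maps are only defined for built variants."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def properties_table(variants: Iterable[SpliceVariant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        p = sequence_properties(v.sequence)
        rows.append({
            "variant": v.name, "length": len(v),
            "n_negative": p.n_negative, "n_positive": p.n_positive,
            "n_his": p.n_his, "net_charge_formal": p.net_charge_formal,
            "epsilon_280": p.epsilon_280,
        })
    return pd.DataFrame(rows).set_index("variant")


def write_pair_mask_json(pairs: Sequence[tuple[int, int]] | set[tuple[int, int]],
                         path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(sorted([list(p) for p in pairs]), fh)
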