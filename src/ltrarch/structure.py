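"""Classify element chains into the five ARH structural variants.

Labels: S1 (ARH directly after the native RH inside pol), S2 (ARH upstream
of RT inside pol), S3 (ARH in its own ORF between gag and pol), S4 (ARH in
its own ORF upstream of gag), S5 (two sequential ARHs after the native RH),
NO_ARH, or UNKNOWN when no rule fires.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._seq import reverse_complement, translate
from .mining import DomainHit, ElementChain
from .synth import GenomeRecord

LABELS = ("S1", "S2", "S3", "S4", "S5", "NO_ARH", "UNKNOWN")


@dataclass(frozen=True)
class StructureCall:
    label: str
    rationale: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


def _element_window(genome: GenomeRecord, chain: ElementChain, pad: int) -> tuple[int, int, str]:
    s, e = chain.span
    w0, w1 = max(0, s - pad), min(len(genome.sequence), e + pad)
    seq = genome.sequence[w0:w1]
    if chain.strand == "-":
        seq = reverse_complement(seq)
    return w0, w1, seq


def _to_element_coords(span: tuple[int, int], w0: int, w1: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return span[0] - w0, span[1] - w0
    return w1 - span[1], w1 - span[0]


def _find_orfs(seq: str, min_orf_aa: int) -> list[tuple[int, int]]:
    """Maximal ATG-to-stop ORFs >= min_orf_aa in the three forward frames of
    ``seq``, as half-open nucleotide intervals, element 5'->3' order."""
    orfs = []
    for f in range(3):
        aa = translate(seq[f:])
        seg_start = 0
        for seg in aa.split("*"):
            m = seg.find("M")
            if m >= 0 and len(seg) - m >= min_orf_aa:
                start = f + 3 * (seg_start + m)
                end = f + 3 * (seg_start + len(seg)) + 3  # include stop codon
                orfs.append((start, min(end, len(seq))))
            seg_start += len(seg) + 1
    orfs.sort()
    return orfs


def assign_orfs(genome: GenomeRecord, chain: ElementChain, min_orf_aa: int = 50, pad: int = 1500) -> ElementChain:
    """Attach an ORF index to each hit.

    ORFs are found on the element strand around the chain span; a hit gets
    the index of the ORF covering >=80% of its span, else None.  Indices are
    in element 5'->3' order.
    """
    if not chain.hits:
        chain.orf_index = []
        return chain
    w0, w1, seq = _element_window(genome, chain, pad)
    orfs = _find_orfs(seq, min_orf_aa)
    assignment: list[int | None] = []
    for h in chain.hits:
        hs, he = _to_element_coords(h.span, w0, w1, chain.strand)
        idx = None
        for i, (os_, oe) in enumerate(orfs):
            overlap = max(0, min(he, oe) - max(hs, os_))
            if overlap >= 0.8 * (he - hs):
                idx = i
                break
        assignment.append(idx)
    chain.orf_index = assignment
    return chain


def _elem_pos(chain: ElementChain, hit: DomainHit) -> tuple[int, int]:
    """Hit span on the element axis (increasing 5'->3')."""
    if chain.strand == "+":
        return hit.span
    s, e = chain.span
    return s + e - hit.span[1], s + e - hit.span[0]


def classify_structure(chain: ElementChain, arh_linker_max: int = 600) -> StructureCall:
    """Apply the variant rules in order on the element-ordered domain chain.

    Requires assign_orfs to have run; a chain whose ARH placement matches no
    rule - or that lacks the native RT/RH needed to anchor the rules - is
    UNKNOWN rather than force-fitted.
    """
    if len(chain.orf_index) != len(chain.hits):
        raise ValueError("run assign_orfs before classify_structure")
    doms = chain.domain_order()
    arh_idx = [i for i, d in enumerate(doms) if d == "ARH"]
    if not arh_idx:
        return StructureCall("NO_ARH", "no ARH hit")

    orf_of = dict(zip(range(len(doms)), chain.orf_index))
    pos = [_elem_pos(chain, h) for h in chain.hits]

    def only_idx(name: str) -> int | None:
        idxs = [i for i, d in enumerate(doms) if d == name]
        return idxs[0] if len(idxs) == 1 else None

    rt_i, rh_i = only_idx("RT"), only_idx("RH")
    gag_i = only_idx("GAG")
    pol_orf = orf_of.get(rt_i) if rt_i is not None else None

    # (b) S5: two ARHs, both after native RH, contiguous, inside pol
    if len(arh_idx) == 2 and rh_i is not None and pol_orf is not None:
        a1, a2 = arh_idx
        if (
            a2 == a1 + 1
            and pos[a1][0] >= pos[rh_i][1]
            and orf_of[a1] == pol_orf
            and orf_of[a2] == pol_orf
            and pos[a1][0] - pos[rh_i][1] <= arh_linker_max
        ):
            return StructureCall("S5", "two sequential ARHs after native RH in pol")

    if len(arh_idx) != 1:
        return StructureCall("UNKNOWN", f"{len(arh_idx)} ARH hits match no variant")
    a = arh_idx[0]
    a_orf = orf_of[a]

    # (c) S1: ARH immediately after native RH, inside pol
    if (
        rh_i is not None
        and pol_orf is not None
        and a_orf == pol_orf
        and -3 <= pos[a][0] - pos[rh_i][1] <= arh_linker_max
        and not any(rh_i < i < a for i in range(len(doms)))
    ):
        return StructureCall("S1", "ARH immediately after native RH in pol")

    # (d) S2: ARH before RT, inside pol
    if rt_i is not None and pol_orf is not None and a_orf == pol_orf and pos[a][1] <= pos[rt_i][0]:
        return StructureCall("S2", "ARH upstream of RT in pol")

    own_orf = a_orf is not None and all(
        orf_of[i] != a_orf for i in range(len(doms)) if i != a
    )

    # (e) S3: ARH in its own ORF between gag and pol
    if (
        own_orf
        and gag_i is not None
        and pol_orf is not None
        and pos[a][0] >= pos[gag_i][1]
        and rt_i is not None
        and pos[a][1] <= min(pos[i][0] for i in range(len(doms)) if orf_of[i] == pol_orf)
    ):
        return StructureCall("S3", "ARH in separate ORF between gag and pol")

    # (f) S4: ARH in its own ORF upstream of gag
    if own_orf and gag_i is not None and pos[a][1] <= pos[gag_i][0]:
        return StructureCall("S4", "ARH in separate ORF upstream of gag")

    return StructureCall("UNKNOWN", "ARH placement matches no variant")


def structure_frequency_table(calls: list[tuple[str, StructureCall]]) -> pd.DataFrame:
    """Per-genome counts and percentages (1 decimal) per label.

    Percentages are over all classified elements, UNKNOWN included.
    """
    if not calls:
        return pd.DataFrame(columns=["genome_id", "label", "count", "percent"])
    df = pd.DataFrame(
        [(g, c.label) for g, c in calls], columns=["genome_id", "label"]
    )
    counts = df.groupby(["genome_id", "label"]).size().rename("count").reset_index()
    totals = counts.groupby("genome_id")["count"].transform("sum")
    counts["percent"] = (100.0 * counts["count"] / totals).round(1)
    return counts.sort_values(["genome_id", "label"]).reset_index(drop=True)
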