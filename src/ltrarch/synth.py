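"""Synthetic genomes with planted LTR retrotransposons and ground truth.

Every element is emitted from an :class:`ElementBlueprint` describing one of
the structural variants (S1-S5, NO_ARH): paired long terminal repeats, a gag
ORF, a pol ORF and - depending on the variant - an additional archaeal-type
RNase H (ARH) domain in one of five placements.  A :class:`PlantedTruth`
record carries every span in genome coordinates so downstream recovery can
be scored exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from ._seq import AA_ALPHABET, STOP_CODONS, SYNONYMOUS_CODONS, reverse_complement

STRUCTURE_LABELS = ("S1", "S2", "S3", "S4", "S5", "NO_ARH")

DOMAIN_NAMES = ("GAG", "PR", "RT", "RH", "ARH", "INT")
DEFAULT_DOMAIN_LENGTHS = {"GAG": 80, "PR": 100, "RT": 200, "RH": 130, "ARH": 130, "INT": 150}

#: canonical catalytic carboxylate core of RNase H-type domains
CATALYTIC_RESIDUES = "DEDD"
#: relative positions of the four catalytic residues along the domain
_CATALYTIC_FRACTIONS = (0.08, 0.35, 0.60, 0.85)
#: substitutions used when a catalytic core is degraded (never D or E)
DEGRADED_RESIDUES = "ANSTG"

# ORF layout per structural variant: each inner list is one ORF, domains in
# element 5'->3' order.  S5 carries proximal then distal ARH after native RH.
STRUCTURE_ORFS: dict[str, list[list[str]]] = {
    "S1": [["GAG"], ["PR", "RT", "RH", "ARH", "INT"]],
    "S2": [["GAG"], ["PR", "ARH", "RT", "RH", "INT"]],
    "S3": [["GAG"], ["ARH"], ["PR", "RT", "RH", "INT"]],
    "S4": [["ARH"], ["GAG"], ["PR", "RT", "RH", "INT"]],
    "S5": [["GAG"], ["PR", "RT", "RH", "ARH", "ARH", "INT"]],
    "NO_ARH": [["GAG"], ["PR", "RT", "RH", "INT"]],
}


class CapacityError(ValueError):
    """Requested elements cannot be placed in the genome."""


@dataclass(frozen=True)
class DomainSpec:
    """Consensus definition of one protein domain."""

    name: str
    length: int
    consensus: str
    catalytic_positions: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if len(self.consensus) != self.length:
            raise ValueError(f"{self.name}: consensus length {len(self.consensus)} != {self.length}")
        for idx, res in self.catalytic_positions:
            if not 0 <= idx < self.length:
                raise ValueError(f"{self.name}: catalytic index {idx} out of range")
            if res not in "DE":
                raise ValueError(f"{self.name}: catalytic residue {res!r} not in {{D,E}}")


@dataclass(frozen=True)
class ElementBlueprint:
    """Recipe for one planted element."""

    structure: str
    ltr_length: int = 300
    ltr_divergence: float = 0.0
    domain_divergence: float = 0.0
    degrade_native_rh: bool = False
    degrade_distal_arh: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURE_LABELS:
            raise ValueError(f"unknown structure {self.structure!r}")
        for name in ("ltr_divergence", "domain_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.5:
                raise ValueError(f"{name}={v} outside [0, 0.5]")
        if self.degrade_distal_arh and self.structure != "S5":
            raise ValueError("degrade_distal_arh requires structure S5")
        if self.ltr_length < 1:
            raise ValueError("ltr_length must be positive")


@dataclass
class PlantedTruth:
    """Ground truth for one planted element, in genome coordinates."""

    element_id: str
    genome_id: str
    span: tuple[int, int]
    strand: str
    structure: str
    ltr_spans: tuple[tuple[int, int], tuple[int, int]]
    domain_spans: list[tuple[str, tuple[int, int]]]
    rh_core_state: str
    arh_core_states: list[str] = field(default_factory=list)

    def shifted(self, offset: int) -> "PlantedTruth":
        sh = lambda sp: (sp[0] + offset, sp[1] + offset)
        return dataclasses.replace(
            self,
            span=sh(self.span),
            ltr_spans=(sh(self.ltr_spans[0]), sh(self.ltr_spans[1])),
            domain_spans=[(n, sh(sp)) for n, sp in self.domain_spans],
        )

    def reflected(self, length: int) -> "PlantedTruth":
        """Truth for the reverse-complemented element of the given length."""
        rf = lambda sp: (length - sp[1], length - sp[0])
        return dataclasses.replace(
            self,
            span=rf(self.span),
            strand="-" if self.strand == "+" else "+",
            ltr_spans=(rf(self.ltr_spans[0]), rf(self.ltr_spans[1])),
            domain_spans=[(n, rf(sp)) for n, sp in self.domain_spans],
        )


@dataclass
class GenomeRecord:
    genome_id: str
    sequence: str
    taxon: str = ""


def _catalytic_indices(length: int) -> tuple[int, ...]:
    return tuple(int(round(f * length)) for f in _CATALYTIC_FRACTIONS)


def make_profile_library(seed: int, lengths: dict[str, int] | None = None) -> list[DomainSpec]:
    """Seed-deterministic consensus library for the six domains.

    RH and ARH both carry the D,E,D,D catalytic core but are forced to differ
    at >=40% of positions so PSSM scoring can tell them apart.
    """
    lengths = dict(DEFAULT_DOMAIN_LENGTHS, **(lengths or {}))
    rng = np.random.default_rng(seed)
    aa = np.array(list(AA_ALPHABET))
    specs: dict[str, DomainSpec] = {}
    consensi: dict[str, np.ndarray] = {}
    for name in DOMAIN_NAMES:
        length = lengths[name]
        cons = rng.choice(aa, size=length)
        cat: tuple[tuple[int, str], ...] = ()
        if name in ("RH", "ARH"):
            idx = _catalytic_indices(length)
            for i, res in zip(idx, CATALYTIC_RESIDUES):
                cons[i] = res
            cat = tuple(zip(idx, CATALYTIC_RESIDUES))
        consensi[name] = cons
        specs[name] = DomainSpec(name=name, length=length, consensus="".join(cons), catalytic_positions=cat)

    # enforce RH/ARH separability: identity must stay below 40%; random
    # draws land near 9%, so the loop is only a guard rail
    rh, arh = consensi["RH"], consensi["ARH"]
    if len(rh) == len(arh):
        frozen = {i for i, _ in specs["ARH"].catalytic_positions}
        while np.mean(rh == arh) >= 0.4:
            same = [i for i in np.flatnonzero(rh == arh) if i not in frozen]
            for i in same:
                choices = [c for c in AA_ALPHABET if c != rh[i]]
                arh[i] = choices[rng.integers(len(choices))]
        specs["ARH"] = dataclasses.replace(specs["ARH"], consensus="".join(arh))
    return [specs[n] for n in DOMAIN_NAMES]


def mutate_protein(seq: str, rate: float, seed: int, frozen: frozenset[int] | set[int] = frozenset()) -> str:
    """Substitute each non-frozen position independently with probability
    ``rate`` to a uniformly chosen different residue."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate={rate} outside [0, 1]")
    for i in frozen:
        if not 0 <= i < len(seq):
            raise ValueError(f"frozen position {i} out of range")
    rng = np.random.default_rng(seed)
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        if i in frozen:
            continue
        choices = [c for c in AA_ALPHABET if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def back_translate(seq: str, seed: int) -> str:
    """DNA encoding ``seq`` with codons chosen uniformly among synonyms."""
    rng = np.random.default_rng(seed)
    codons = []
    for res in seq:
        if res not in SYNONYMOUS_CODONS or res == "*":
            raise ValueError(f"cannot back-translate residue {res!r}")
        options = SYNONYMOUS_CODONS[res]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _mutate_dna(dna: str, rate: float, rng: np.random.Generator) -> str:
    out = list(dna)
    for i in np.flatnonzero(rng.random(len(dna)) < rate):
        choices = [c for c in "ACGT" if c != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _scrub_start_codons(dna: str) -> str:
    """Remove every ATG so a stretch cannot seed a spurious ORF."""
    while "ATG" in dna:
        dna = dna.replace("ATG", "ATC")
    return dna


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.4) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(np.array(list("ACGT")), size=length, p=p))


def _spacer(rng: np.random.Generator, lo: int = 20, hi: int = 200) -> str:
    return _scrub_start_codons(_random_dna(rng, int(rng.integers(lo, hi + 1))))


def build_element(
    blueprint: ElementBlueprint,
    library: list[DomainSpec],
    seed: int,
    element_id: str = "element",
) -> tuple[str, PlantedTruth]:
    """Emit one element (5'LTR + ORFs + 3'LTR) and its ground truth.

    The coding region is a sequence of ATG..stop ORFs whose translations
    contain the blueprint's domain chain; catalytic cores are frozen during
    divergence mutation so the planted core state is exact.
    """
    specs = {s.name: s for s in library}
    missing = set(DOMAIN_NAMES) - set(specs)
    if missing:
        raise ValueError(f"library missing domains: {sorted(missing)}")
    rng = np.random.default_rng([seed, blueprint.seed])

    ltr1 = _scrub_start_codons(_random_dna(rng, blueprint.ltr_length))
    ltr2 = _mutate_dna(ltr1, blueprint.ltr_divergence, rng)

    parts: list[str] = [ltr1]
    pos = len(ltr1)
    utr5 = _spacer(rng)
    parts.append(utr5)
    pos += len(utr5)

    domain_spans: list[tuple[str, tuple[int, int]]] = []
    rh_core_state = CATALYTIC_RESIDUES
    arh_core_states: list[str] = []
    n_arh_seen = 0
    n_arh_total = sum(orf.count("ARH") for orf in STRUCTURE_ORFS[blueprint.structure])

    for orf_i, orf_domains in enumerate(STRUCTURE_ORFS[blueprint.structure]):
        aa_parts: list[str] = ["M"]
        aa_pos = 1
        orf_spans: list[tuple[str, tuple[int, int]]] = []  # aa coords within ORF
        for dom_name in orf_domains:
            spec = specs[dom_name]
            seq = spec.consensus
            frozen = frozenset(i for i, _ in spec.catalytic_positions)
            degrade = (dom_name == "RH" and blueprint.degrade_native_rh) or (
                dom_name == "ARH"
                and blueprint.degrade_distal_arh
                and n_arh_seen == n_arh_total - 1  # distal = last ARH in element order
            )
            core = list(CATALYTIC_RESIDUES) if spec.catalytic_positions else []
            if degrade:
                chars = list(seq)
                for k, (idx, _res) in enumerate(spec.catalytic_positions):
                    sub = DEGRADED_RESIDUES[rng.integers(len(DEGRADED_RESIDUES))]
                    chars[idx] = sub
                    core[k] = sub
                seq = "".join(chars)
            seq = mutate_protein(seq, blueprint.domain_divergence, int(rng.integers(2**31)), frozen=frozen)
            orf_spans.append((dom_name, (aa_pos, aa_pos + len(seq))))
            aa_parts.append(seq)
            aa_pos += len(seq)
            linker = "".join(
                AA_ALPHABET[j] for j in rng.integers(len(AA_ALPHABET), size=int(rng.integers(4, 13)))
            )
            aa_parts.append(linker)
            aa_pos += len(linker)
            if dom_name == "RH":
                rh_core_state = "".join(core)
            elif dom_name == "ARH":
                arh_core_states.append("".join(core))
                n_arh_seen += 1
        orf_aa = "".join(aa_parts)
        orf_dna = back_translate(orf_aa, int(rng.integers(2**31))) + STOP_CODONS[rng.integers(len(STOP_CODONS))]
        for dom_name, (a0, a1) in orf_spans:
            domain_spans.append((dom_name, (pos + 3 * a0, pos + 3 * a1)))
        parts.append(orf_dna)
        pos += len(orf_dna)
        if orf_i < len(STRUCTURE_ORFS[blueprint.structure]) - 1:
            sp = _spacer(rng)
            parts.append(sp)
            pos += len(sp)

    utr3 = _spacer(rng)
    parts.append(utr3)
    pos += len(utr3)
    parts.append(ltr2)
    total = pos + len(ltr2)

    dna = "".join(parts)
    assert len(dna) == total
    truth = PlantedTruth(
        element_id=element_id,
        genome_id="",
        span=(0, total),
        strand="+",
        structure=blueprint.structure,
        ltr_spans=((0, len(ltr1)), (pos, total)),
        domain_spans=domain_spans,
        rh_core_state=rh_core_state,
        arh_core_states=arh_core_states,
    )
    return dna, truth


def plant_elements(
    genome_length: int,
    blueprints: list[ElementBlueprint],
    gc: float,
    seed: int,
    library: list[DomainSpec] | None = None,
    genome_id: str = "genome",
    taxon: str = "",
    edge_margin: int = 6000,
    min_separation: int = 6000,
    max_tries: int = 500,
) -> tuple[GenomeRecord, list[PlantedTruth]]:
    """Place elements at non-overlapping positions in i.i.d. background.

    Reverse-strand elements are reverse-complemented; truth coordinates are
    genome coordinates.  ``edge_margin`` keeps elements clear of contig ends
    so LTR flank extraction is never edge-truncated by construction, and
    ``min_separation`` keeps inter-element gaps above the default chaining
    ``max_gap`` so neighbouring elements never merge into one chain.
    """
    rng = np.random.default_rng(seed)
    if library is None:
        library = make_profile_library(int(rng.integers(2**31)))
    built = [
        build_element(bp, library, seed=int(rng.integers(2**31)), element_id=f"{genome_id}.e{i}")
        for i, bp in enumerate(blueprints)
    ]
    total_len = sum(len(d) for d, _ in built)
    if total_len > 0.8 * genome_length:
        raise CapacityError(
            f"elements total {total_len} bp exceed 80% of genome length {genome_length}"
        )

    # choose non-overlapping starts by rejection sampling
    placed: list[tuple[int, int]] = []
    starts: list[int] = []
    for dna, _truth in built:
        lo, hi = edge_margin, genome_length - edge_margin - len(dna)
        if hi < lo:
            raise CapacityError("genome too short for element plus edge margins")
        for _ in range(max_tries):
            s = int(rng.integers(lo, hi + 1))
            span = (s - min_separation, s + len(dna) + min_separation)
            if all(span[1] <= a or span[0] >= b for a, b in placed):
                placed.append(span)
                starts.append(s)
                break
        else:
            raise CapacityError("could not place elements without overlap")

    background = _random_dna(rng, genome_length, gc=gc)
    genome = list(background)
    truths: list[PlantedTruth] = []
    for (dna, truth), start in zip(built, starts):
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            dna = reverse_complement(dna)
            truth = truth.reflected(len(dna))
        truth = truth.shifted(start)
        truth.genome_id = genome_id
        genome[start : start + len(dna)] = dna
        truths.append(truth)
    truths.sort(key=lambda t: t.span)
    return GenomeRecord(genome_id=genome_id, sequence="".join(genome), taxon=taxon), truths
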