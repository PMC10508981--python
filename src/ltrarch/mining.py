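"""Recover planted elements from raw sequence.

The stage mirrors a domain-first retrotransposon miner: protein domains are
located by gapless PSSM scanning of all six reading frames, same-strand hits
are chained into candidate elements, terminal repeats are detected by
seed-and-extend between the chain flanks, and near-identical copies are
preclustered on RT amino-acid identity with one representative per cluster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import AA_ALPHABET, AA_INDEX, frame_to_genomic, reverse_complement, translate
from .synth import DomainSpec, GenomeRecord

UNIFORM_BACKGROUND = np.full(20, 1 / 20)

#: log-odds score assigned to residues outside the 20-letter alphabet (X etc.)
UNKNOWN_RESIDUE_SCORE = 0.0
#: floor replacing -inf scores when pseudocount is 0 and a residue is unseen
SCORE_FLOOR = -20.0


@dataclass
class DomainProfile:
    """Per-position log-odds matrix (bits) for one protein domain."""

    name: str
    matrix: np.ndarray  # L x 20
    background: np.ndarray  # 20
    consensus: str
    catalytic_positions: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.consensus), 20):
            raise ValueError("matrix shape does not match consensus length")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def self_score(self) -> float:
        idx = [AA_INDEX[a] for a in self.consensus]
        return float(self.matrix[np.arange(len(self)), idx].sum())


@dataclass
class DomainHit:
    profile_name: str
    genome_id: str
    strand: str
    span: tuple[int, int]  # forward-strand, 0-based half-open
    frame: int
    score: float
    matched_aa: str


@dataclass
class LTRPair:
    span5: tuple[int, int]
    span3: tuple[int, int]
    identity: float  # percent
    length: int  # alignment columns


@dataclass
class ElementChain:
    chain_id: str
    genome_id: str
    strand: str
    hits: list[DomainHit]  # element 5'->3' order
    orf_index: list[int | None] = field(default_factory=list)
    ltr: LTRPair | None = None
    edge_truncated: bool = False

    @property
    def span(self) -> tuple[int, int]:
        return min(h.span[0] for h in self.hits), max(h.span[1] for h in self.hits)

    @property
    def full_span(self) -> tuple[int, int]:
        """Chain span widened to the LTR pair when one was found."""
        s, e = self.span
        if self.ltr is not None:
            s = min(s, self.ltr.span5[0], self.ltr.span3[0])
            e = max(e, self.ltr.span5[1], self.ltr.span3[1])
        return s, e

    def domain_order(self) -> list[str]:
        return [h.profile_name for h in self.hits]

    def hit_for(self, name: str) -> DomainHit | None:
        best = None
        for h in self.hits:
            if h.profile_name == name and (best is None or h.score > best.score):
                best = h
        return best


def build_pssm(
    alignment: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    name: str = "profile",
    catalytic_positions: tuple[tuple[int, str], ...] = (),
) -> DomainProfile:
    """PSSM from a gapped amino-acid alignment.

    score[i][a] = log2((count_i(a) + pc*bg[a]) / (total_i + pc) / bg[a]);
    gap characters are excluded from the counts.
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("ragged alignment")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, dtype=float)
    counts = np.zeros((width, 20))
    for row in alignment:
        for i, res in enumerate(row.upper()):
            j = AA_INDEX.get(res)
            if j is not None:
                counts[i, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        matrix = np.log2((counts + pseudocount * bg) / (totals + pseudocount) / bg)
    matrix = np.maximum(matrix, SCORE_FLOOR)
    consensus = "".join(AA_ALPHABET[j] for j in matrix.argmax(axis=1))
    return DomainProfile(
        name=name, matrix=matrix, background=bg, consensus=consensus,
        catalytic_positions=catalytic_positions,
    )


def profile_from_spec(spec: DomainSpec, pseudocount: float = 1.0) -> DomainProfile:
    prof = build_pssm([spec.consensus], pseudocount=pseudocount, name=spec.name,
                      catalytic_positions=spec.catalytic_positions)
    prof.consensus = spec.consensus
    return prof


def six_frame_translate(dna: str) -> list[tuple[int, str]]:
    """Translations of frames +1,+2,+3,-1,-2,-3 with frame metadata."""
    dna = dna.upper()
    rc = reverse_complement(dna)
    out = []
    for f in (1, 2, 3):
        out.append((f, translate(dna[f - 1 :])))
    for f in (1, 2, 3):
        out.append((-f, translate(rc[f - 1 :])))
    return out


def _encode(aa: str) -> tuple[np.ndarray, np.ndarray]:
    """Residue indices (20 = unknown) and a stop-codon mask."""
    codes = np.fromiter((AA_INDEX.get(c, 20) for c in aa), dtype=np.int64, count=len(aa))
    stars = np.fromiter((c == "*" for c in aa), dtype=bool, count=len(aa))
    return codes, stars


def scan_profile(aa: str, profile: DomainProfile, min_bits: float) -> list[tuple[int, float]]:
    """Gapless sliding-window scan.

    Returns greedily-selected non-overlapping windows with score >= min_bits;
    windows containing a stop are discarded.
    """
    L = len(profile)
    n = len(aa) - L + 1
    if n <= 0:
        return []
    codes, stars = _encode(aa)
    ext = np.hstack([profile.matrix, np.full((L, 1), UNKNOWN_RESIDUE_SCORE)])
    scores = np.zeros(n)
    for i in range(L):
        scores += ext[i, codes[i : i + n]]
    star_cum = np.concatenate([[0], np.cumsum(stars)])
    has_star = (star_cum[L:] - star_cum[:-L]) > 0
    ok = np.flatnonzero((scores >= min_bits) & ~has_star)
    # greedy by score, then by offset for determinism
    order = ok[np.lexsort((ok, -scores[ok]))]
    chosen: list[tuple[int, float]] = []
    taken = np.zeros(len(aa), dtype=bool)
    for o in order:
        if not taken[o : o + L].any():
            taken[o : o + L] = True
            chosen.append((int(o), float(scores[o])))
    chosen.sort()
    return chosen


def mine_domains(
    genome: GenomeRecord,
    profiles: list[DomainProfile],
    min_bits_frac: float = 0.4,
) -> list[DomainHit]:
    """Scan all six frames with every profile; threshold is a fraction of
    each profile's self-score."""
    hits: list[DomainHit] = []
    frames = six_frame_translate(genome.sequence)
    n = len(genome.sequence)
    for frame, aa in frames:
        for prof in profiles:
            thr = min_bits_frac * prof.self_score
            for offset, score in scan_profile(aa, prof, thr):
                span = frame_to_genomic(frame, offset, len(prof), n)
                hits.append(
                    DomainHit(
                        profile_name=prof.name,
                        genome_id=genome.genome_id,
                        strand="+" if frame > 0 else "-",
                        span=span,
                        frame=frame,
                        score=score,
                        matched_aa=aa[offset : offset + len(prof)],
                    )
                )
    hits.sort(key=lambda h: (h.span, h.profile_name))
    return hits


def _dedupe_overlapping(hits: list[DomainHit]) -> list[DomainHit]:
    """Resolve overlapping same-profile hits to the higher score."""
    kept: list[DomainHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.span)):
        clash = any(
            k.profile_name == h.profile_name
            and k.span[0] < h.span[1]
            and h.span[0] < k.span[1]
            for k in kept
        )
        if not clash:
            kept.append(h)
    return kept


def chain_hits(hits: list[DomainHit], max_gap: int = 10_000) -> list[ElementChain]:
    """Single-linkage chaining of same-strand hits with gaps <= max_gap."""
    genomes = {h.genome_id for h in hits}
    if len(genomes) > 1:
        raise ValueError("chain_hits expects hits from a single genome")
    chains: list[ElementChain] = []
    for strand in ("+", "-"):
        sh = sorted((h for h in hits if h.strand == strand), key=lambda h: h.span)
        group: list[DomainHit] = []
        groups: list[list[DomainHit]] = []
        end = None
        for h in sh:
            if end is not None and h.span[0] - end > max_gap:
                groups.append(group)
                group = []
            group.append(h)
            end = max(end, h.span[1]) if end is not None else h.span[1]
        if group:
            groups.append(group)
        for g in groups:
            g = _dedupe_overlapping(g)
            g.sort(key=lambda h: h.span, reverse=(strand == "-"))
            chains.append(
                ElementChain(chain_id="", genome_id=g[0].genome_id, strand=strand, hits=g)
            )
    chains.sort(key=lambda c: c.span)
    for i, c in enumerate(chains):
        c.chain_id = f"{c.genome_id}.c{i}"
    return chains


# ---------------------------------------------------------------------------
# LTR detection: exact k-mer seeds between the two flanks, co-diagonal seed
# chaining, banded global alignment of the chained region, exact outward
# extension.  The generator introduces substitutions only, so the banded
# alignment is effectively diagonal; the band absorbs rare indels in real data.

def _maximal_matches(a: str, b: str, k: int = 20) -> list[tuple[int, int, int]]:
    """Maximal exact matches >= k between a and b as (i, j, length)."""
    index: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        index.setdefault(a[i : i + k], []).append(i)
    seen: set[tuple[int, int]] = set()
    out = []
    for j in range(len(b) - k + 1):
        for i in index.get(b[j : j + k], ()):
            diag = j - i
            # extend to maximal match
            s_i, s_j = i, j
            while s_i > 0 and s_j > 0 and a[s_i - 1] == b[s_j - 1]:
                s_i -= 1
                s_j -= 1
            e_i, e_j = i + k, j + k
            while e_i < len(a) and e_j < len(b) and a[e_i] == b[e_j]:
                e_i += 1
                e_j += 1
            key = (diag, s_i)
            if key not in seen:
                seen.add(key)
                out.append((s_i, s_j, e_i - s_i))
    return out


def _banded_global(a: str, b: str, band: int = 20,
                   match: int = 1, mismatch: int = -1, gap: int = -2) -> tuple[int, int]:
    """Banded Needleman-Wunsch; returns (matches, alignment columns)."""
    n, m = len(a), len(b)
    if abs(n - m) > band:
        band = abs(n - m) + band
    NEG = -(10**9)
    # dp[i][d] with d = j - i + band
    width = 2 * band + 1
    dp = np.full((n + 1, width), NEG, dtype=np.int64)
    ptr = np.zeros((n + 1, width), dtype=np.int8)  # 0 diag, 1 up(del a), 2 left(ins b)
    for i in range(n + 1):
        jlo = max(0, i - band)
        jhi = min(m, i + band)
        for j in range(jlo, jhi + 1):
            d = j - i + band
            if i == 0 and j == 0:
                dp[i, d] = 0
                continue
            best, p = NEG, 0
            if i > 0 and j > 0:
                s = dp[i - 1, d] + (match if a[i - 1] == b[j - 1] else mismatch)
                if s > best:
                    best, p = s, 0
            if i > 0 and d + 1 < width:
                s = dp[i - 1, d + 1] + gap
                if s > best:
                    best, p = s, 1
            if j > 0 and d - 1 >= 0:
                s = dp[i, d - 1] + gap
                if s > best:
                    best, p = s, 2
            dp[i, d] = best
            ptr[i, d] = p
    i, j = n, m
    matches = cols = 0
    while i > 0 or j > 0:
        d = j - i + band
        p = ptr[i, d]
        if i > 0 and j > 0 and p == 0:
            matches += a[i - 1] == b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and p == 1:
            i -= 1
        else:
            j -= 1
        cols += 1
    return matches, cols


def find_ltrs(
    genome: GenomeRecord,
    chain: ElementChain,
    flank: int = 5000,
    min_len: int = 100,
    min_identity: float = 80.0,
    k: int = 20,
    band: int = 20,
) -> LTRPair | None:
    """Detect the terminal-repeat pair flanking a chain.

    Marks the chain edge-truncated (and reports no LTR) when the flank would
    run past a contig edge.
    """
    if flank < min_len:
        raise ValueError("flank must be >= min_len")
    s, e = chain.span
    seq = genome.sequence
    if s - flank < 0 or e + flank > len(seq):
        chain.edge_truncated = True
        return None
    up = seq[s - flank : s]
    down = seq[e : e + flank]
    seeds = _maximal_matches(up, down, k=k)
    if not seeds:
        return None
    best = max(seeds, key=lambda t: (t[2], -t[0]))
    diag = best[1] - best[0]
    co = [t for t in seeds if abs((t[1] - t[0]) - diag) <= band]
    i0 = min(t[0] for t in co)
    j0 = min(t[1] for t in co)
    i1 = max(t[0] + t[2] for t in co)
    j1 = max(t[1] + t[2] for t in co)
    # exact outward extension
    while i0 > 0 and j0 > 0 and up[i0 - 1] == down[j0 - 1]:
        i0 -= 1
        j0 -= 1
    while i1 < len(up) and j1 < len(down) and up[i1] == down[j1]:
        i1 += 1
        j1 += 1
    matches, cols = _banded_global(up[i0:i1], down[j0:j1], band=band)
    if cols < min_len:
        return None
    identity = 100.0 * matches / cols
    if identity < min_identity:
        return None
    pair = LTRPair(
        span5=(s - flank + i0, s - flank + i1),
        span3=(e + j0, e + j1),
        identity=identity,
        length=cols,
    )
    chain.ltr = pair
    return pair


CORE_DOMAINS = ("GAG", "PR", "RT", "RH", "INT")


def completeness_score(chain: ElementChain) -> float:
    """0.8 * (core domains present)/5 + 0.2 * [LTR pair present]."""
    found = {h.profile_name for h in chain.hits} & set(CORE_DOMAINS)
    return 0.8 * len(found) / 5 + 0.2 * (chain.ltr is not None)


@dataclass
class Precluster:
    members: list[ElementChain]
    representative: ElementChain
    no_rt: bool = False


def precluster_by_rt(
    chains: list[ElementChain],
    identity_threshold: float = 80.0,
) -> list[Precluster]:
    """Single-linkage clustering on pairwise RT amino-acid identity.

    Chains lacking an RT hit pass through as flagged singletons.  The
    representative is the highest completeness score; ties break to the
    longer chain span, then lexicographic chain id.
    """
    from .phylo import align_pair, pairwise_identity

    with_rt = [(c, c.hit_for("RT").matched_aa) for c in chains if c.hit_for("RT") is not None]
    without = [c for c in chains if c.hit_for("RT") is None]

    n = len(with_rt)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = align_pair(with_rt[i][1], with_rt[j][1])
            if pairwise_identity(ra, rb) >= identity_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[ElementChain]] = {}
    for i, (c, _) in enumerate(with_rt):
        groups.setdefault(find(i), []).append(c)

    def rep_key(c: ElementChain) -> tuple:
        return (-completeness_score(c), -(c.span[1] - c.span[0]), c.chain_id)

    out = [
        Precluster(members=members, representative=min(members, key=rep_key))
        for members in groups.values()
    ]
    out.sort(key=lambda p: p.representative.chain_id)
    out.extend(Precluster(members=[c], representative=c, no_rt=True) for c in without)
    return out
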