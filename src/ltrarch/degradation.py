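"""Catalytic-core readout for RNase H-type domains.

A candidate domain is globally aligned to its reference profile, the residues
mapped onto the four canonical catalytic positions (the D,E,D,D core) are
read out, and the domain is called degraded when it has lost at least
``degraded_threshold`` of them — the tether-like state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import AA_INDEX
from .mining import DomainProfile

GAP_PENALTY = -4.0  # bits per gapped column, linear


@dataclass
class ProfileAlignment:
    score: float
    #: consensus position -> sequence position (None where the profile
    #: column is deleted in the sequence)
    position_map: list[int | None]
    aligned_consensus: str
    aligned_seq: str


@dataclass
class RHAssessment:
    domain_id: str
    core_state: str  # 4 residues, '-' where gapped
    intact_count: int
    degraded: bool
    severity: int


def align_to_profile(seq: str, profile: DomainProfile, gap: float = GAP_PENALTY) -> ProfileAlignment:
    """Global alignment of ``seq`` to the profile consensus.

    Substitution scores come straight from the profile's log-odds columns;
    gaps are linear.  Traceback prefers diagonal, then deletion, for
    determinism.
    """
    if not seq:
        raise ValueError("empty sequence")
    L = len(profile)
    n = len(seq)
    codes = np.fromiter((AA_INDEX.get(c, -1) for c in seq), dtype=np.int64, count=n)
    sub = np.hstack([profile.matrix, np.zeros((L, 1))])  # unknown residue -> 0
    dp = np.empty((L + 1, n + 1))
    ptr = np.zeros((L + 1, n + 1), dtype=np.int8)  # 0 diag, 1 up (del), 2 left (ins)
    dp[0, :] = gap * np.arange(n + 1)
    dp[:, 0] = gap * np.arange(L + 1)
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    for i in range(1, L + 1):
        diag = dp[i - 1, :-1] + sub[i - 1, codes]
        up = dp[i - 1, 1:] + gap
        row = dp[i]
        prev_best = np.maximum(diag, up)
        ptr[i, 1:] = np.where(diag >= up, 0, 1)
        # left moves resolved sequentially within the row
        best = row[0]
        for j in range(1, n + 1):
            left = best + gap
            if prev_best[j - 1] >= left:
                row[j] = prev_best[j - 1]
            else:
                row[j] = left
                ptr[i, j] = 2
            best = row[j]
    i, j = L, n
    pmap: list[int | None] = [None] * L
    ac, asq = [], []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if i > 0 and j > 0 and p == 0:
            pmap[i - 1] = j - 1
            ac.append(profile.consensus[i - 1])
            asq.append(seq[j - 1])
            i, j = i - 1, j - 1
        elif i > 0 and (p == 1 or j == 0):
            ac.append(profile.consensus[i - 1])
            asq.append("-")
            i -= 1
        else:
            ac.append("-")
            asq.append(seq[j - 1])
            j -= 1
    return ProfileAlignment(
        score=float(dp[L, n]),
        position_map=pmap,
        aligned_consensus="".join(reversed(ac)),
        aligned_seq="".join(reversed(asq)),
    )


def catalytic_core_state(
    seq: str,
    profile: DomainProfile,
    domain_id: str = "",
    degraded_threshold: int = 1,
) -> RHAssessment:
    """Read the residues at the four catalytic positions and call degradation."""
    if len(profile.catalytic_positions) != 4:
        raise ValueError(f"profile {profile.name} lacks 4 catalytic position annotations")
    aln = align_to_profile(seq, profile)
    state = []
    intact = 0
    for pos, canonical in profile.catalytic_positions:
        j = aln.position_map[pos]
        res = "-" if j is None else seq[j]
        state.append(res)
        intact += res == canonical
    severity = 4 - intact
    return RHAssessment(
        domain_id=domain_id,
        core_state="".join(state),
        intact_count=intact,
        degraded=severity >= degraded_threshold,
        severity=severity,
    )


def degradation_report(
    assessments: list[tuple[str, str, RHAssessment]],
) -> pd.DataFrame:
    """Summary per (structure label, domain role).

    ``assessments`` rows are (structure, role, assessment) with role in
    {native_RH, aRH_proximal, aRH_distal}; empty groups are simply absent.
    """
    if not assessments:
        return pd.DataFrame(columns=["structure", "role", "n", "mean_severity", "fraction_degraded"])
    df = pd.DataFrame(
        [(s, r, a.severity, a.degraded) for s, r, a in assessments],
        columns=["structure", "role", "severity", "degraded"],
    )
    out = (
        df.groupby(["structure", "role"])
        .agg(n=("severity", "size"), mean_severity=("severity", "mean"),
             fraction_degraded=("degraded", "mean"))
        .reset_index()
    )
    return out.sort_values(["structure", "role"]).reset_index(drop=True)
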