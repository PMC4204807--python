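"""De novo detection of tandem and interspersed amino-acid repeats.

185/333 polypeptides carry short (roughly 8-30 aa) sequence repeats, some
back-to-back (tandem) and some separated by intervening sequence
(interspersed).  Detection is by gapless self-comparison: exact k-mer seeds
define diagonals of the self-comparison matrix, seeds are extended along
their diagonal while the mismatch fraction stays within budget, and the
resulting copy intervals are clustered into repeat types by motif
similarity.  Copy numbers and arrangements are then summarised per family.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .seqio import SequenceRecord


@dataclass(frozen=True)
class RepeatCopy:
    start: int  # 0-based half-open aa coordinates
    end: int
    partial: bool = False  # shorter than the type's motif (>=60% of it)

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "RepeatCopy") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class RepeatHit:
    seq_id: str
    type_id: int
    copies: list[RepeatCopy]
    arrangement: str  # {"tandem", "interspersed"}
    consensus_motif: str

    @property
    def n_copies(self) -> int:
        return len(self.copies)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _diagonal_intervals(seq: str, d: int, k: int, max_mm: float, min_len: int):
    """Maximal well-scoring intervals along self-comparison diagonal d.

    An interval [a, b) means seq[a:b] matches seq[a+d:b+d] gaplessly with
    mismatch fraction <= max_mm; it must contain an exact k-mer seed and
    start/end on matching positions.
    """
    n = len(seq) - d
    if n < k:
        return []
    match = [seq[x] == seq[x + d] for x in range(n)]
    # runs of consecutive matches
    runs = []
    x = 0
    while x < n:
        if match[x]:
            y = x
            while y < n and match[y]:
                y += 1
            runs.append((x, y))
            x = y
        else:
            x += 1
    seeded = [r for r in runs if r[1] - r[0] >= k]
    if not seeded:
        return []
    intervals = []
    used_runs: set[int] = set()
    run_index = {r: i for i, r in enumerate(runs)}
    for r in seeded:
        if run_index[r] in used_runs:
            continue
        a, b = r
        mm = 0
        # greedily absorb neighbouring runs (paying the mismatch gap between
        # them) while the overall mismatch fraction stays within budget;
        # alternate right/left so detection is symmetric under reversal
        idx = run_index[r]
        lo_idx, hi_idx = idx, idx
        changed = True
        while changed:
            changed = False
            for direction in (1, -1):
                j = hi_idx + 1 if direction == 1 else lo_idx - 1
                if not (0 <= j < len(runs)):
                    continue
                nxt = runs[j]
                if direction == 1:
                    gap = nxt[0] - b
                    new_a, new_b = a, nxt[1]
                else:
                    gap = a - nxt[1]
                    new_a, new_b = nxt[0], b
                new_mm = mm + gap
                if new_mm / (new_b - new_a) <= max_mm:
                    a, b, mm = new_a, new_b, new_mm
                    if direction == 1:
                        hi_idx = j
                    else:
                        lo_idx = j
                    changed = True
        for j in range(lo_idx, hi_idx + 1):
            used_runs.add(j)
        if b - a >= min_len or (b - a >= d and d >= k):
            intervals.append((a, b))
    return intervals


def _linear_identity(x: str, y: str) -> float:
    n = min(len(x), len(y))
    if n == 0:
        return 0.0
    return sum(1 for i in range(n) if x[i] == y[i]) / n


def _refine_tandem(seq: str, d: int, a: int, b: int, max_mm: float):
    """Cut a period-``d`` tandem interval into copies at the best phase.

    Diagonal extension can creep a few positions into unrelated flanking
    sequence, shifting the apparent phase of the array.  Every phase is
    tried; copies are windows whose identity to the phase consensus is
    within the mismatch budget, and the phase admitting the most (then
    best-matching) copies wins.  Flanking partial copies (>= 60% of the
    period) are appended with a partial flag.
    """
    lo = max(0, a - d)
    hi = min(len(seq), b + 2 * d)
    thresh = 1 - max_mm
    best = None
    for o in range(d):
        starts = [p for p in range(lo + o, hi - d + 1, d)]
        if len(starts) < 2:
            continue
        rows = [seq[p : p + d] for p in starts]
        M = _consensus(rows)
        accepted = [p for p in starts if _linear_identity(seq[p : p + d], M) >= thresh]
        if len(accepted) < 2:
            continue
        M = _consensus([seq[p : p + d] for p in accepted])
        accepted = [p for p in starts if _linear_identity(seq[p : p + d], M) >= thresh]
        if len(accepted) < 2:
            continue
        score = (
            len(accepted),
            sum(_linear_identity(seq[p : p + d], M) for p in accepted),
        )
        if best is None or score > best[0]:
            best = (score, accepted, M)
    if best is None:
        return None
    _, accepted, M = best
    copies = [(p, p + d, False) for p in accepted]
    # flanking partial copies
    first, last = accepted[0], accepted[-1]
    k = min(d, first - lo)
    if k >= 0.6 * d and _linear_identity(seq[first - k : first], M[d - k :]) >= thresh:
        copies.insert(0, (first - k, first, True))
    k = min(d, len(seq) - (last + d))
    if k >= 0.6 * d and _linear_identity(
        seq[last + d : last + d + k], M[:k]
    ) >= thresh:
        copies.append((last + d, last + d + k, True))
    return d, copies


def _copies_from_interval(seq: str, d: int, a: int, b: int, min_len: int, max_mm: float):
    """Turn a diagonal interval into copy intervals.

    Overlapping diagonals (b - a >= d) are tandem arrays with period d,
    refined by :func:`_refine_tandem`; otherwise the interval names two
    separated copies of length b - a.
    Returns (motif_len, [(start, end, partial)]).
    """
    if b - a >= d:
        if d < min_len:
            return None
        return _refine_tandem(seq, d, a, b, max_mm)
    if b - a < min_len:
        return None
    return b - a, [(a, b, False), (a + d, b + d, False)]


def _identity(x: str, y: str) -> float:
    """Best gapless identity over relative offsets of the two motifs.

    The phase of a tandem array and the exact extension boundaries are
    arbitrary, so the same repeat type may surface shifted or rotated in
    different sequences; identity is the best matches/overlap over all
    offsets with an overlap of at least 60% of the shorter motif (minimum
    5 aa).
    """
    if len(x) > len(y):
        x, y = y, x
    if not x:
        return 0.0
    doubled = y + y
    best = 0
    for o in range(len(y)):
        best = max(
            best,
            sum(1 for i, a in enumerate(x) if a == doubled[o + i]),
        )
    return best / len(x)


def _consensus(seqs: list[str]) -> str:
    """Majority-rule consensus over same-start gapless copies, at the modal
    copy length (ties to the shorter)."""
    lengths = sorted(s and len(s) for s in seqs)
    modal = max(set(lengths), key=lambda l: (lengths.count(l), -l))
    cols = []
    for i in range(modal):
        chars = [s[i] for s in seqs if len(s) > i]
        cols.append(max(sorted(set(chars)), key=chars.count))
    return "".join(cols)


def find_repeats(
    prot: SequenceRecord,
    min_len: int = 8,
    max_mismatch_frac: float = 0.2,
    k: int = 5,
    tandem_gap: int = 2,
) -> list[RepeatHit]:
    """Detect repeated amino-acid motifs within one polypeptide.

    Returns one :class:`RepeatHit` per repeat type, copies sorted by start,
    type ids numbered by first-copy position.  A type is ``tandem`` iff
    every gap between consecutive copies is <= ``tandem_gap`` aa.
    """
    seq = prot.ungapped().rstrip("*")
    groups: list[tuple[int, list[tuple[int, int, bool]]]] = []
    for d in range(1, len(seq)):
        for a, b in _diagonal_intervals(seq, d, k, max_mismatch_frac, min_len):
            got = _copies_from_interval(seq, d, a, b, min_len, max_mismatch_frac)
            if got:
                groups.append(got)
    if not groups:
        return []

    # flatten copies; union-find joins copies in the same group and copies
    # that overlap >=50% of the shorter one (duplicates across diagonals)
    copies: list[tuple[int, int, bool]] = []
    owner: list[int] = []
    for gi, (_, cs) in enumerate(groups):
        for c in copies_sorted(cs):
            copies.append(c)
            owner.append(gi)
    uf = _UnionFind(len(copies))
    first_of_group: dict[int, int] = {}
    for ci, gi in enumerate(owner):
        if gi in first_of_group:
            uf.union(ci, first_of_group[gi])
        else:
            first_of_group[gi] = ci
    for i in range(len(copies)):
        for j in range(i + 1, len(copies)):
            ov = max(
                0, min(copies[i][1], copies[j][1]) - max(copies[i][0], copies[j][0])
            )
            longer = max(copies[i][1] - copies[i][0], copies[j][1] - copies[j][0])
            # near-coincident copies only: a short partial overlapping a
            # different type's copy must not chain the clusters together
            if longer and ov / longer >= 0.8:
                uf.union(i, j)

    clusters: dict[int, list[int]] = defaultdict(list)
    for ci in range(len(copies)):
        clusters[uf.find(ci)].append(ci)

    # within each cluster keep a non-redundant copy tiling (shortest first)
    hits = []
    for members in clusters.values():
        cand = sorted(
            (copies[ci] for ci in members),
            key=lambda c: (c[1] - c[0], c[0]),
        )
        kept: list[tuple[int, int, bool]] = []
        for c in cand:
            redundant = False
            for kc in kept:
                ov = max(0, min(c[1], kc[1]) - max(c[0], kc[0]))
                shorter = min(c[1] - c[0], kc[1] - kc[0])
                if shorter and ov / shorter >= 0.5:
                    redundant = True
                    break
            if not redundant:
                kept.append(c)
        kept.sort(key=lambda c: c[0])
        if len(kept) < 2:
            continue
        seqs = [seq[a:b] for a, b, _ in kept]
        motif = _consensus(seqs)
        # a sub-motif-length copy must still look like the motif; boundary
        # creep into unrelated neighbouring sequence is discarded here
        kept = [
            c
            for c in kept
            if c[1] - c[0] >= len(motif)
            or _identity(seq[c[0] : c[1]], motif) >= 1 - max_mismatch_frac
        ]
        if len(kept) < 2:
            continue
        seqs = [seq[a:b] for a, b, _ in kept]
        motif = _consensus(seqs)
        kept2 = [
            RepeatCopy(a, b, partial=(b - a) < len(motif) or p)
            for a, b, p in kept
        ]
        gaps_ok = all(
            kept2[i + 1].start - kept2[i].end <= tandem_gap
            for i in range(len(kept2) - 1)
        )
        hits.append(
            RepeatHit(
                seq_id=prot.id,
                type_id=0,
                copies=kept2,
                arrangement="tandem" if gaps_ok else "interspersed",
                consensus_motif=motif,
            )
        )

    # merge types whose consensus motifs are near-identical
    if len(hits) > 1:
        uf2 = _UnionFind(len(hits))
        for i in range(len(hits)):
            for j in range(i + 1, len(hits)):
                if _identity(hits[i].consensus_motif, hits[j].consensus_motif) >= (
                    1 - max_mismatch_frac
                ):
                    uf2.union(i, j)
        merged: dict[int, RepeatHit] = {}
        for i, h in enumerate(hits):
            r = uf2.find(i)
            if r in merged:
                prev = merged[r]
                # shortest-first dedup, as in the per-cluster pass, so the
                # fundamental-period copies win over doubled-period ones
                allc = sorted(
                    set(prev.copies) | set(h.copies),
                    key=lambda c: (len(c), c.start),
                )
                dedup: list[RepeatCopy] = []
                for c in allc:
                    if any(
                        c.overlap(kc) >= 0.5 * min(len(c), len(kc))
                        for kc in dedup
                    ):
                        continue
                    dedup.append(c)
                dedup.sort(key=lambda c: c.start)
                gaps_ok = all(
                    dedup[t + 1].start - dedup[t].end <= tandem_gap
                    for t in range(len(dedup) - 1)
                )
                shorter_motif = min(
                    (prev.consensus_motif, h.consensus_motif), key=len
                )
                merged[r] = RepeatHit(
                    seq_id=prot.id,
                    type_id=0,
                    copies=dedup,
                    arrangement="tandem" if gaps_ok else "interspersed",
                    consensus_motif=shorter_motif,
                )
            else:
                merged[r] = h
        hits = list(merged.values())

    hits.sort(key=lambda h: h.copies[0].start)
    for t, h in enumerate(hits, start=1):
        h.type_id = t
    return hits


def copies_sorted(cs):
    return sorted(cs, key=lambda c: c[0])


def scan_motifs(
    prot: SequenceRecord,
    motifs: dict[str, str],
    max_mismatch_frac: float = 0.2,
    tandem_gap: int = 2,
) -> list[RepeatHit]:
    """Scan a polypeptide for known repeat motifs (validation mode).

    Slides each motif along the sequence and reports non-overlapping
    windows with identity >= 1 - max_mismatch_frac, greedily from the best
    match.  Motif names are preserved; a hit needs >= 1 copy (unlike de
    novo detection, a single occurrence of a known motif is meaningful).
    """
    seq = prot.ungapped().rstrip("*")
    hits = []
    for t, (name, motif) in enumerate(sorted(motifs.items()), start=1):
        L = len(motif)
        scored = []
        for i in range(len(seq) - L + 1):
            ident = sum(1 for a, b in zip(seq[i : i + L], motif) if a == b) / L
            if ident >= 1 - max_mismatch_frac:
                scored.append((ident, i))
        scored.sort(key=lambda s: (-s[0], s[1]))
        taken: list[int] = []
        for _, i in scored:
            if all(abs(i - j) >= L for j in taken):
                taken.append(i)
        if not taken:
            continue
        taken.sort()
        copies = [RepeatCopy(i, i + L) for i in taken]
        gaps_ok = all(
            copies[x + 1].start - copies[x].end <= tandem_gap
            for x in range(len(copies) - 1)
        )
        hits.append(
            RepeatHit(
                seq_id=prot.id,
                type_id=t,
                copies=copies,
                arrangement="tandem" if gaps_ok else "interspersed",
                consensus_motif=motif,
            )
        )
    return hits


def repeat_census(
    hits_by_seq: dict[str, list[RepeatHit]],
    max_mismatch_frac: float = 0.2,
) -> pd.DataFrame:
    """Family-level repeat census.

    Per-sequence repeat types are unified across the family by consensus-
    motif identity (>= 1 - max_mismatch_frac), then summarised as one row
    per family type: family_type_id, max_copy_number, motif length and the
    number of repeat-bearing sequences.
    """
    flat: list[tuple[str, RepeatHit]] = [
        (sid, h) for sid, hs in hits_by_seq.items() for h in hs
    ]
    if not flat:
        return pd.DataFrame(
            columns=["family_type_id", "max_copy_number", "length", "n_sequences"]
        )
    uf = _UnionFind(len(flat))
    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if _identity(
                flat[i][1].consensus_motif, flat[j][1].consensus_motif
            ) >= (1 - max_mismatch_frac):
                uf.union(i, j)
    clusters: dict[int, list[int]] = defaultdict(list)
    for i in range(len(flat)):
        clusters[uf.find(i)].append(i)
    rows = []
    for root in sorted(clusters, key=lambda r: min(clusters[r])):
        members = clusters[root]
        motifs = [flat[i][1].consensus_motif for i in members]
        rows.append(
            {
                "family_type_id": len(rows) + 1,
                "max_copy_number": max(flat[i][1].n_copies for i in members),
                "length": len(_consensus(motifs)),
                "n_sequences": len({flat[i][0] for i in members}),
            }
        )
    return pd.DataFrame(rows)


def repeat_hits_to_df(hits_by_seq: dict[str, list[RepeatHit]]) -> pd.DataFrame:
    rows = []
    for sid, hs in hits_by_seq.items():
        for h in hs:
            for c in h.copies:
                rows.append(
                    {
                        "seq_id": sid,
                        "type_id": h.type_id,
                        "start_1based": c.start + 1,
                        "end_1based": c.end,
                        "partial": int(c.partial),
                        "arrangement": h.arrangement,
                        "consensus_motif": h.consensus_motif,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "seq_id", "type_id", "start_1based", "end_1based",
            "partial", "arrangement", "consensus_motif",
        ],
    )
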