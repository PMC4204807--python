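"""Synthetic mosaic gene families with known ground truth.

The generator emulates the structure of 185/333-type immune gene families:
a library of conserved elements (15-111 bp, frame-preserving), element
patterns as ordered subsets of the library, a 63-bp leader encoding the
signal peptide, within-family divergence along a random coalescent tree
(SNPs that never create stop codons), short in-frame background deletions,
planted frameshifts (1-2 nt) and premature stop codons at configured
rates, amino-acid repeat motifs planted inside designated elements, and -
in gene mode - an intron with its own element library and Greek-named
patterns splitting the leader at position 55/56.

Because indels are realised as deletions, the gapped alignment is emitted
directly with exact truth coordinates; no re-alignment step exists to blur
the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from skbio import TreeNode

from .mosaic import alpha_name, greek_name
from .seqio import GAP, MsAlignment, SequenceRecord, write_fasta

SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
STOPS = ("TAA", "TAG", "TGA")

# codons per amino acid for planting repeat motifs
from Bio.Data.CodonTable import standard_dna_table as _tbl  # noqa: E402

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in _tbl.forward_table.items():
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_aa].sort()

UTR5 = "TCTCTTGGCAGAC"  # ends in the 5' half of the Kozak context
UTR3 = "TGGAAAAGACATC"


@dataclass(frozen=True)
class RepeatSpec:
    """A planted amino-acid repeat: motif, copy number, arrangement."""

    motif: str
    copies: int
    arrangement: str = "tandem"  # {"tandem", "interspersed"}


# four synthetic default repeat types (stand-ins shaped like the family's
# short glycine/arginine-rich repeats; the published motifs are not bundled)
DEFAULT_REPEATS = (
    RepeatSpec("GRGDNQGGFN", 3, "tandem"),
    RepeatSpec("HGGRNPDD", 4, "tandem"),
    RepeatSpec("QGPRGDNG", 2, "interspersed"),
    RepeatSpec("GGRPQQNFHD", 2, "tandem"),
)


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic family generator.

    Element lengths span the family's printed extremes (15-111 bp, both
    multiples of 3); the intron size range and the 63-bp leader split at
    55/56 likewise mirror the printed gene anatomy.  Defect rates sum to
    roughly the family's defective fraction (11 of 112).
    """

    n_elements: int = 12
    element_len_range: tuple[int, int] = (15, 111)
    n_patterns: int = 6
    pattern_occupancy: float = 0.8
    n_sequences: int = 30
    snp_rate: float = 0.02  # expected root-to-tip substitutions/site
    indel_rate: float = 0.5  # expected in-frame background deletions/seq
    indel_len_choices: tuple[int, ...] = (3, 6, 9, 12)
    frameshift_rate: float = 0.05
    premature_stop_rate: float = 0.05
    repeat_motifs: tuple[RepeatSpec, ...] = DEFAULT_REPEATS
    gene_mode: bool = False
    n_intron_elements: int = 10
    n_intron_patterns: int = 4
    intron_len_range: tuple[int, int] = (457, 1392)
    intron_element_len_range: tuple[int, int] = (60, 140)
    leader_len: int = 63
    leader_split: int = 55  # intron interrupts the leader after this base
    tree_depth: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for r in (
            self.pattern_occupancy, self.snp_rate, self.frameshift_rate,
            self.premature_stop_rate,
        ):
            if not 0 <= r <= 1:
                raise ValueError(f"rate {r} outside [0, 1]")
        lo, hi = self.element_len_range
        if lo > hi or lo < 15:
            raise ValueError("element_len_range must be ordered and >= 15")
        for spec in self.repeat_motifs:
            need = spec.copies * len(spec.motif) * 3
            if spec.arrangement == "tandem" and need > hi:
                raise ValueError(
                    f"tandem repeat {spec.motif!r} x{spec.copies} needs "
                    f"{need} bp, larger than the largest element ({hi})"
                )
        if self.n_patterns < 1 or self.n_elements < 2:
            raise ValueError("need >= 2 elements and >= 1 pattern")


@dataclass
class SeqTruth:
    seq_id: str
    pattern_index: int
    pattern_name: str
    presence: tuple[bool, ...]
    frameshift_at: Optional[int] = None  # ungapped nt position
    premature_stop_codon: Optional[int] = None  # codon index
    intron_pattern_index: Optional[int] = None
    intron_pattern_name: Optional[str] = None


@dataclass
class SynthTruth:
    element_lengths: list[int]
    element_bounds: list[int]  # cumulative column boundaries incl leader
    leader_len: int
    patterns: list[tuple[bool, ...]]
    per_seq: list[SeqTruth]
    tree_newick: str
    repeat_specs: tuple[RepeatSpec, ...]
    repeat_hosts: dict[int, list[int]]  # repeat index -> host element indices
    intron_element_lengths: list[int] = field(default_factory=list)
    intron_patterns: list[tuple[bool, ...]] = field(default_factory=list)
    intron_span: Optional[tuple[int, int]] = None

    def expected_boundaries(self) -> set[int]:
        """Columns where the set of pattern-absent sequences changes: the
        boundaries any gap-based segmentation can recover."""
        realized = {t.pattern_index for t in self.per_seq}
        pats = [self.patterns[i] for i in sorted(realized)]
        bounds = set()
        n_units = len(self.element_lengths) + 1  # leader + elements
        for b in range(1, n_units):
            left = b - 1
            right = b
            absent_left = frozenset(
                i for i, p in enumerate(pats)
                if left > 0 and not p[left - 1]
            )
            absent_right = frozenset(
                i for i, p in enumerate(pats) if not p[right - 1]
            )
            if absent_left != absent_right:
                bounds.add(self.element_bounds[b])
        return bounds


@dataclass
class SynthFamily:
    sequences: list[SequenceRecord]  # unaligned cDNAs with UTRs
    alignment: MsAlignment  # gapped ORF (+terminal stop) alignment
    truth: SynthTruth
    gene_alignment: Optional[MsAlignment] = None
    intron_span: Optional[tuple[int, int]] = None


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _random_sense_codons(rng, n: int) -> str:
    return "".join(SENSE[i] for i in rng.integers(0, len(SENSE), size=n))


def _encode_protein(rng, aa_seq: str) -> str:
    return "".join(
        _CODONS_FOR_AA[a][rng.integers(len(_CODONS_FOR_AA[a]))]
        for a in aa_seq
    )


def _coalescent_tree(rng, ids: list[str], depth: float) -> TreeNode:
    """Random Kingman-shaped tree, root height normalised to ``depth``."""
    nodes = [TreeNode(name=i) for i in ids]
    heights = [0.0] * len(nodes)
    h = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        h += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode()
        a.length = h - heights[i]
        b.length = h - heights[j]
        parent.extend([a, b])
        nodes = [n for t, n in enumerate(nodes) if t not in (i, j)] + [parent]
        heights = [x for t, x in enumerate(heights) if t not in (i, j)] + [h]
    root = nodes[0]
    scale = depth / h if h > 0 else 1.0
    for n in root.traverse(include_self=False):
        n.length = (n.length or 0.0) * scale
    return root


def _mutate(rng, seq: list[str], p: float, orf_end: int) -> None:
    """In-place substitutions at per-site probability ``p``; sites within
    the ORF (columns < orf_end) never mutate into a stop codon."""
    L = len(seq)
    n_mut = rng.binomial(L, p)
    if n_mut == 0:
        return
    sites = rng.choice(L, size=n_mut, replace=False)
    for s in sites:
        cur = seq[s]
        alts = [b for b in "ACGT" if b != cur]
        if s < orf_end:
            cp = s % 3
            c0 = s - cp
            codon = seq[c0 : c0 + 3]
            ok = []
            for b in alts:
                trial = codon.copy()
                trial[cp] = b
                if "".join(trial) not in STOPS:
                    ok.append(b)
            alts = ok
        if alts:
            seq[s] = alts[rng.integers(len(alts))]


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_family(cfg: GeneratorConfig) -> SynthFamily:
    """Generate a synthetic mosaic family with full ground truth."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- element library -------------------------------------------------
    lo, hi = cfg.element_len_range
    lengths = [
        3 * int(rng.integers(lo // 3, hi // 3 + 1))
        for _ in range(cfg.n_elements)
    ]

    # assign repeat hosts: tandem types occupy one element sized to fit;
    # interspersed types place one copy in each of two distinct elements
    host_of: dict[int, list[int]] = {}
    free = list(range(cfg.n_elements))
    for ri, spec in enumerate(cfg.repeat_motifs):
        need = 2 if spec.arrangement == "interspersed" else 1
        if len(free) <= need + 1:
            raise ValueError("not enough elements to host the repeat motifs")
        picks = []
        for _ in range(need):
            # keep first and last elements repeat-free (pattern anchors)
            cand = [e for e in free if 0 < e < cfg.n_elements - 1]
            if not cand:
                raise ValueError("not enough internal elements for repeats")
            e = cand[rng.integers(len(cand))]
            free.remove(e)
            picks.append(e)
        host_of[ri] = picks
        if spec.arrangement == "tandem":
            lengths[picks[0]] = spec.copies * len(spec.motif) * 3
        else:
            for e in picks:
                lengths[e] = max(lengths[e], len(spec.motif) * 3 + 6)

    elements: list[str] = [
        _random_sense_codons(rng, l // 3) for l in lengths
    ]
    for ri, spec in enumerate(cfg.repeat_motifs):
        unit = _encode_protein(rng, spec.motif)
        if spec.arrangement == "tandem":
            e = host_of[ri][0]
            elements[e] = unit * spec.copies
        else:
            for e in host_of[ri]:
                body = elements[e]
                elements[e] = unit + body[len(unit) :]

    # --- leader (21 codons, ATG first, Kozak +4 G) -----------------------
    n_leader_codons = cfg.leader_len // 3
    leader = "ATG" + "G" + _random_sense_codons(rng, n_leader_codons)[4:]
    # ensure no stop slipped in through the splice above
    leader_codons = [leader[i : i + 3] for i in range(0, cfg.leader_len, 3)]
    for ci, c in enumerate(leader_codons[1:], start=1):
        if c in STOPS:
            leader_codons[ci] = "GGA"
    leader = "".join(leader_codons)[: cfg.leader_len]

    # --- element patterns -------------------------------------------------
    patterns: list[tuple[bool, ...]] = [tuple([True] * cfg.n_elements)]
    tries = 0
    while len(patterns) < cfg.n_patterns:
        tries += 1
        if tries > 1000:
            raise ValueError("could not draw enough distinct patterns")
        p = [bool(rng.random() < cfg.pattern_occupancy) for _ in range(cfg.n_elements)]
        p[0] = p[-1] = True
        p = tuple(p)
        if p not in patterns:
            patterns.append(p)

    # --- column layout ----------------------------------------------------
    bounds = [0, cfg.leader_len]
    for l in lengths:
        bounds.append(bounds[-1] + l)
    stop_codon = "TAA"
    root_seq = leader + "".join(elements) + stop_codon
    orf_end = len(root_seq)  # stop included; frame-safe mutation region ends
    ncols = len(root_seq)

    # --- intron (gene mode) ----------------------------------------------
    intron_lengths: list[int] = []
    intron_patterns: list[tuple[bool, ...]] = []
    intron_elements: list[str] = []
    if cfg.gene_mode:
        ilo, ihi = cfg.intron_element_len_range
        tlo, thi = cfg.intron_len_range
        for _ in range(1000):
            intron_lengths = [
                int(rng.integers(ilo, ihi + 1))
                for _ in range(cfg.n_intron_elements)
            ]
            if tlo <= sum(intron_lengths) <= thi:
                break
        intron_elements = [
            "".join(
                "ACGT"[b] for b in rng.integers(0, 4, size=l)
            )
            for l in intron_lengths
        ]
        intron_patterns = [tuple([True] * cfg.n_intron_elements)]
        tries = 0
        while len(intron_patterns) < cfg.n_intron_patterns:
            tries += 1
            if tries > 1000:
                raise ValueError("could not draw distinct intron patterns")
            p = [bool(rng.random() < 0.7) for _ in range(cfg.n_intron_elements)]
            p[0] = p[-1] = True
            p = tuple(p)
            if p not in intron_patterns and tlo <= sum(
                l for l, keep in zip(intron_lengths, p) if keep
            ):
                intron_patterns.append(p)

    # --- assign patterns & defects to sequences ---------------------------
    ids = [f"syn{n:03d}" for n in range(cfg.n_sequences)]
    pat_idx = [0] + [
        int(rng.integers(len(patterns))) for _ in range(cfg.n_sequences - 1)
    ]
    intron_idx = (
        [0]
        + [
            int(rng.integers(len(intron_patterns)))
            for _ in range(cfg.n_sequences - 1)
        ]
        if cfg.gene_mode
        else [None] * cfg.n_sequences
    )

    # premature stops are only planted upstream of the last boundary any
    # gap-based segmentation can see (stops inside the terminal element are
    # by definition not premature under the final-element rule)
    realized = sorted({i for i in pat_idx})
    rpats = [patterns[i] for i in realized]
    seen_bounds = []
    for b in range(1, cfg.n_elements + 1):
        absent_left = frozenset(
            i for i, p in enumerate(rpats) if b - 1 > 0 and not p[b - 2]
        )
        absent_right = frozenset(i for i, p in enumerate(rpats) if not p[b - 1])
        if absent_left != absent_right:
            seen_bounds.append(bounds[b])
    last_boundary = max(seen_bounds) if seen_bounds else 0

    # --- evolve along the coalescent tree ---------------------------------
    tree = _coalescent_tree(rng, ids, cfg.tree_depth)
    full_intron = "".join(intron_elements)
    evolve_template = root_seq + full_intron  # intron appended for evolution
    seqs_at: dict[int, list[str]] = {id(tree): list(evolve_template)}
    for node in tree.preorder(include_self=False):
        child = list(seqs_at[id(node.parent)])
        _mutate(rng, child, (node.length or 0.0) * cfg.snp_rate, orf_end)
        seqs_at[id(node)] = child
    leaf_seq = {t.name: seqs_at[id(t)] for t in tree.tips()}

    host_elements = {e for picks in host_of.values() for e in picks}
    per_seq: list[SeqTruth] = []
    aligned_rows: list[str] = []
    intron_rows: list[str] = []
    raw_records: list[SequenceRecord] = []

    for n, sid in enumerate(ids):
        chars = list(leaf_seq[sid][: len(root_seq)])
        intron_chars = list(leaf_seq[sid][len(root_seq) :])
        pres = patterns[pat_idx[n]]

        # absent elements -> gap blocks
        for e, keep in enumerate(pres):
            if not keep:
                s, t = bounds[e + 1], bounds[e + 2]
                for c in range(s, t):
                    chars[c] = GAP

        # elements available for mutating events: present, internal,
        # repeat-free; each hosts at most one event so gap runs never merge
        avail = [
            e
            for e, keep in enumerate(pres)
            if keep and e not in host_elements and 0 < e < cfg.n_elements - 1
        ]

        def _pop_random(pool: list[int]) -> int:
            e = pool[rng.integers(len(pool))]
            pool.remove(e)
            return e

        # background in-frame deletions (length 3k < min element length, a
        # 3-column margin keeps them clear of element boundaries)
        n_indels = rng.poisson(cfg.indel_rate)
        for _ in range(n_indels):
            if not avail:
                break
            e = _pop_random(avail)
            ln = int(
                cfg.indel_len_choices[rng.integers(len(cfg.indel_len_choices))]
            )
            s, t = bounds[e + 1], bounds[e + 2]
            # deletion must leave well over half the element covered so it
            # can never flip the element's presence call
            if t - s < ln + 6 or ln > 0.4 * (t - s):
                continue
            start = s + 3 * int(rng.integers(1, (t - s - ln) // 3))
            for c in range(start, start + ln):
                chars[c] = GAP

        fs_at = None
        stop_at = None
        if avail and rng.random() < cfg.frameshift_rate:
            e = _pop_random(avail)
            ln = int(rng.integers(1, 3))  # 1 or 2 nt
            s, t = bounds[e + 1], bounds[e + 2]
            pos = int(rng.integers(s + 3, t - 3 - ln))
            for c in range(pos, pos + ln):
                chars[c] = GAP
            fs_at = sum(1 for c in chars[:pos] if c != GAP)
        elif avail and rng.random() < cfg.premature_stop_rate:
            stop_pool = [e for e in avail if bounds[e + 2] <= last_boundary]
            if stop_pool:
                e = _pop_random(stop_pool)
                avail.remove(e)
                s, t = bounds[e + 1], bounds[e + 2]
                codon_col = s + 3 * int(rng.integers(1, (t - s) // 3 - 1))
                chars[codon_col : codon_col + 3] = list("TAA")
                stop_at = sum(1 for c in chars[:codon_col] if c != GAP) // 3

        aligned_rows.append("".join(chars))

        if cfg.gene_mode:
            ipres = intron_patterns[intron_idx[n]]
            ioff = 0
            for e, (l, keep) in enumerate(zip(intron_lengths, ipres)):
                if not keep:
                    for c in range(ioff, ioff + l):
                        intron_chars[c] = GAP
                ioff += l
            intron_rows.append("".join(intron_chars))

        ungapped = "".join(c for c in chars if c != GAP)
        raw_records.append(
            SequenceRecord(id=sid, seq=UTR5 + ungapped + UTR3, moltype="dna")
        )
        per_seq.append(
            SeqTruth(
                seq_id=sid,
                pattern_index=pat_idx[n],
                pattern_name=alpha_name(pat_idx[n]),
                presence=pres,
                frameshift_at=fs_at,
                premature_stop_codon=stop_at,
                intron_pattern_index=intron_idx[n],
                intron_pattern_name=(
                    greek_name(intron_idx[n]) if cfg.gene_mode else None
                ),
            )
        )

    alignment = MsAlignment(
        [
            SequenceRecord(id=sid, seq=row, moltype="dna")
            for sid, row in zip(ids, aligned_rows)
        ]
    )

    gene_alignment = None
    intron_span = None
    if cfg.gene_mode:
        split = cfg.leader_split
        gene_rows = [
            row[:split] + irow + row[split:]
            for row, irow in zip(aligned_rows, intron_rows)
        ]
        gene_alignment = MsAlignment(
            [
                SequenceRecord(id=sid, seq=row, moltype="dna")
                for sid, row in zip(ids, gene_rows)
            ]
        )
        intron_span = (split, split + len(full_intron))

    truth = SynthTruth(
        element_lengths=lengths,
        element_bounds=bounds,
        leader_len=cfg.leader_len,
        patterns=patterns,
        per_seq=per_seq,
        tree_newick=str(tree),
        repeat_specs=cfg.repeat_motifs,
        repeat_hosts=host_of,
        intron_element_lengths=intron_lengths,
        intron_patterns=intron_patterns,
        intron_span=intron_span,
    )
    return SynthFamily(
        sequences=raw_records,
        alignment=alignment,
        truth=truth,
        gene_alignment=gene_alignment,
        intron_span=intron_span,
    )


# ---------------------------------------------------------------------------
# deterministic fixtures
# ---------------------------------------------------------------------------

def make_fixtures(outdir) -> dict[str, str]:
    """Write the deterministic toy fixtures used across the test suite.

    Returns a mapping of fixture name -> file path.  Regeneration is
    byte-identical (fixed seeds).  The repeat motif set is a synthetic
    stand-in for the family's four published repeat types (which are not
    bundled); the filename says so.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    # toy gapped MSA with one shared 18-column gap block
    toy = [
        SequenceRecord("t1", "ACGTACGTACGTACGTACGT" + "ACGTACGTACGTACGTAC" + "GTACGTACGTACGTACGTACGT", "dna"),
        SequenceRecord("t2", "ACGTACGTACGTACGTACGT" + "ACGTACGTACGTACGTAC" + "GTACGTACGTACGTACGTACGT", "dna"),
        SequenceRecord("t3", "ACGTACGTACGTACGTACGT" + "-" * 18 + "GTACGTACGTACGTACGTACGT", "dna"),
        SequenceRecord("t4", "ACGTACGTACGTACGTACGT" + "-" * 18 + "GTACGTACGTACGTACGTACGT", "dna"),
    ]
    p = os.path.join(outdir, "toy_msa.fasta")
    write_fasta(toy, p)
    paths["toy_msa"] = p

    # additive 4-taxon distance matrix from the tree ((a:2,b:3):1,(c:4,d:5))
    import pandas as pd

    ids = ["a", "b", "c", "d"]
    dm = pd.DataFrame(
        [
            [0.0, 5.0, 7.0, 8.0],
            [5.0, 0.0, 8.0, 9.0],
            [7.0, 8.0, 0.0, 9.0],
            [8.0, 9.0, 9.0, 0.0],
        ],
        index=ids,
        columns=ids,
    )
    p = os.path.join(outdir, "additive_dm.tsv")
    dm.to_csv(p, sep="\t", index_label="id")
    paths["additive_dm"] = p

    # 2-taxon codon pair (30 codons, a few syn/nonsyn differences)
    rng = np.random.default_rng(42)
    codons = [SENSE[i] for i in rng.integers(0, len(SENSE), size=30)]
    a = "".join(codons)
    b_codons = list(codons)
    b_codons[3] = "GGA" if b_codons[3] != "GGA" else "GGT"
    b_codons[11] = "TTA" if b_codons[11] != "TTA" else "CTA"
    b = "".join(b_codons)
    p = os.path.join(outdir, "codon_pair.fasta")
    write_fasta(
        [SequenceRecord("x", a, "dna"), SequenceRecord("y", b, "dna")], p
    )
    paths["codon_pair"] = p

    # repeat-bearing toy protein: 4x tandem motif in a random background
    rng = np.random.default_rng(7)
    aas = "ACDEFGHIKLMNPQRSTVWY"
    bg1 = "".join(aas[i] for i in rng.integers(0, 20, size=40))
    bg2 = "".join(aas[i] for i in rng.integers(0, 20, size=40))
    prot = bg1 + "GRGDNQGGFN" * 4 + bg2
    p = os.path.join(outdir, "repeat_protein.fasta")
    write_fasta([SequenceRecord("rp1", prot, "protein")], p)
    paths["repeat_protein"] = p

    # synthetic stand-in motif set (the published motif set is not bundled)
    p = os.path.join(outdir, "repeat_types_synthetic.fasta")
    write_fasta(
        [
            SequenceRecord(f"type{i+1}", spec.motif, "protein")
            for i, spec in enumerate(DEFAULT_REPEATS)
        ],
        p,
    )
    paths["repeat_types_synthetic"] = p
    return paths
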