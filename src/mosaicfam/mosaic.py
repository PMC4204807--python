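"""Mosaic element segmentation and element-pattern nomenclature.

185/333-type immune genes are mosaics of conserved sequence blocks
("elements") shared by subsets of the family.  In a multiple alignment an
element that a sequence lacks appears as a long shared gap block, so element
boundaries are exactly the columns where the set of sequences carrying a
long gap run changes.  This module segments a gapped alignment into such
elements, assigns each sequence its element pattern (ordered
presence/absence vector) with alphabetic names, applies the same machinery
to intron alignments (Greek-letter pattern names), and combines exon and
intron patterns into compound gene patterns such as ``E-α``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .seqio import GAP, MsAlignment

GREEK = "αβγδεζηθικλμνξοπρστυφχψω"

CONSENSUS_NAME = "consensus"


def alpha_name(i: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA', 28 -> 'AC' (Excel-style)."""
    name = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 26)
        name = chr(ord("A") + r) + name
    return name


def greek_name(i: int) -> str:
    """0 -> 'α', 23 -> 'ω', 24 -> 'αα' (Greek-letter analogue)."""
    name = ""
    i += 1
    while i > 0:
        i, r = divmod(i - 1, 24)
        name = GREEK[r] + name
    return name


@dataclass(frozen=True)
class Element:
    element_id: str
    start: int  # 0-based half-open alignment columns
    end: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ElementMap:
    """Ordered, non-overlapping element intervals tiling an alignment.

    Every retained column belongs to exactly one element.  ``source``
    distinguishes exon maps (elements ``1..n``, optional leader ``L``) from
    intron maps (elements ``i1..in``).
    """

    elements: list[Element]
    source: str = "exon"  # {"exon", "intron"}
    retained_columns: list[int] | None = None  # original columns kept after
    # all-gap-column removal; None when nothing was dropped

    def __post_init__(self) -> None:
        prev_end = None
        for e in self.elements:
            if e.start >= e.end:
                raise ValueError(f"empty element interval {e}")
            if prev_end is not None and e.start != prev_end:
                raise ValueError(
                    f"elements do not tile: gap/overlap at column {e.start}"
                )
            prev_end = e.end

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def ncols(self) -> int:
        return self.elements[-1].end - self.elements[0].start

    def __iter__(self):
        return iter(self.elements)

    def __getitem__(self, i: int) -> Element:
        return self.elements[i]


@dataclass(frozen=True)
class ElementPattern:
    seq_id: str
    presence: tuple[bool, ...]
    pattern_name: str


@dataclass(frozen=True)
class GenePattern:
    seq_id: str
    exon_pattern: str
    intron_pattern: str

    @property
    def combined_name(self) -> str:
        return f"{self.exon_pattern}-{self.intron_pattern}"


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _long_gap_membership(aln: MsAlignment, min_gap: int) -> list[frozenset[int]]:
    """Per column, the set of row indices whose gap run covering that column
    has length >= min_gap."""
    ncols = aln.ncols
    member: list[set[int]] = [set() for _ in range(ncols)]
    for i, rec in enumerate(aln.records):
        j = 0
        s = rec.seq
        while j < ncols:
            if s[j] == GAP:
                k = j
                while k < ncols and s[k] == GAP:
                    k += 1
                if k - j >= min_gap:
                    for c in range(j, k):
                        member[c].add(i)
                j = k
            else:
                j += 1
    return [frozenset(m) for m in member]


def segment_alignment(
    aln: MsAlignment,
    min_gap: int = 15,
    min_element_len: int = 15,
    leader_len: int | None = None,
) -> ElementMap:
    """Segment a gapped alignment into mosaic elements.

    A boundary is placed wherever the set of sequences having a gap run of
    length >= ``min_gap`` changes; maximal runs of columns with a constant
    set form candidate elements.  Candidates shorter than
    ``min_element_len`` are merged into the neighbour with which more
    sequences share gap status (ties merge left).  Elements are numbered
    ``1..n`` in column order; if ``leader_len`` is given, the first
    ``leader_len`` columns are reserved as the leader element ``L`` and
    segmentation applies to the remainder.

    Columns that are gap in every sequence are dropped with a warning
    before segmentation; the map records the retained original columns.
    """
    if aln.nrows == 0:
        raise ValueError("empty alignment")
    clean, kept = aln.drop_all_gap_columns()
    if len(kept) < aln.ncols:
        warnings.warn(
            f"dropped {aln.ncols - len(kept)} all-gap column(s) before "
            "segmentation"
        )
    if clean.ncols < min_element_len:
        raise ValueError(
            f"alignment has {clean.ncols} usable columns, fewer than "
            f"min_element_len={min_element_len}"
        )

    offset = 0
    if leader_len is not None:
        if not 0 < leader_len < clean.ncols:
            raise ValueError(f"leader_len {leader_len} out of range")
        offset = leader_len

    member = _long_gap_membership(clean, min_gap)[offset:]
    ncols = len(member)

    # candidate segments: maximal constant-membership column runs
    segments: list[tuple[int, int, frozenset[int]]] = []
    start = 0
    for j in range(1, ncols + 1):
        if j == ncols or member[j] != member[start]:
            segments.append((start, j, member[start]))
            start = j

    # merge sub-minimum segments; shortest first, leftmost on ties
    while len(segments) > 1:
        lens = [e - s for s, e, _ in segments]
        short = [i for i, l in enumerate(lens) if l < min_element_len]
        if not short:
            break
        i = min(short, key=lambda i: (lens[i], i))
        nrows = clean.nrows
        if i == 0:
            j = 1
        elif i == len(segments) - 1:
            j = i - 1
        else:
            sig = segments[i][2]
            left, right = segments[i - 1][2], segments[i + 1][2]
            agree_left = nrows - len(sig ^ left)
            agree_right = nrows - len(sig ^ right)
            j = i - 1 if agree_left >= agree_right else i + 1
        a, b = sorted((i, j))
        s0, _, siga = segments[a]
        _, e1, sigb = segments[b]
        # merged segment keeps the signature of the (longer) neighbour
        keep_sig = segments[j][2]
        segments[a : b + 1] = [(s0, e1, keep_sig)]

    elements = []
    if leader_len is not None:
        elements.append(Element("L", 0, leader_len))
    for k, (s, e, _) in enumerate(segments, start=1):
        elements.append(Element(str(k), s + offset, e + offset))
    return ElementMap(
        elements=elements,
        source="exon",
        retained_columns=None if len(kept) == aln.ncols else kept,
    )


# ---------------------------------------------------------------------------
# Pattern assignment
# ---------------------------------------------------------------------------

def assign_patterns(
    aln: MsAlignment,
    emap: ElementMap,
    presence_threshold: float = 0.5,
    naming: str = "latin",
) -> list[ElementPattern]:
    """Assign each sequence its element presence/absence pattern.

    An element is present in a sequence iff non-gap characters cover at
    least ``presence_threshold`` of its columns.  Unique presence vectors
    are named in order of first occurrence (``A, B, ... Z, AA, ...`` or
    Greek ``α, β, ...``); the all-present consensus pattern is emitted
    first under the reserved name ``consensus`` and does not consume a
    name.
    """
    if emap.retained_columns is not None:
        aln = aln.take_columns(emap.retained_columns)
    namer = alpha_name if naming == "latin" else greek_name
    names: dict[tuple[bool, ...], str] = {}
    out = [
        ElementPattern(
            seq_id=CONSENSUS_NAME,
            presence=tuple(True for _ in emap.elements),
            pattern_name=CONSENSUS_NAME,
        )
    ]
    for rec in aln.records:
        pres = []
        for e in emap.elements:
            nongap = sum(1 for c in rec.seq[e.start : e.end] if c != GAP)
            pres.append(nongap >= presence_threshold * len(e))
        key = tuple(pres)
        if key not in names:
            names[key] = namer(len(names))
        out.append(ElementPattern(rec.id, key, names[key]))
    return out


# ---------------------------------------------------------------------------
# Introns and gene patterns
# ---------------------------------------------------------------------------

def segment_introns(
    gene_aln: MsAlignment,
    intron_span: tuple[int, int] | None = None,
    min_gap: int = 15,
    min_element_len: int = 15,
    presence_threshold: float = 0.5,
) -> tuple[ElementMap, list[ElementPattern]]:
    """Segment the intron region of a gene alignment into intron elements.

    ``intron_span`` gives the intron's (start, end) alignment columns
    (0-based half-open), e.g. from known splice sites.  The same
    segmentation algorithm is applied to those columns; elements are
    labelled ``i1..in`` and patterns named by Greek letters α, β, γ, δ ...
    """
    if intron_span is None:
        raise ValueError(
            "intron splice coordinates are required (no exon anchors to "
            "detect them from)"
        )
    start, end = intron_span
    if not 0 <= start < end <= gene_aln.ncols:
        raise ValueError(f"intron span {intron_span} outside alignment")
    sub = gene_aln.slice_columns(start, end)
    emap = segment_alignment(sub, min_gap=min_gap, min_element_len=min_element_len)
    emap = ElementMap(
        elements=[
            Element(f"i{k}", e.start, e.end)
            for k, e in enumerate(emap.elements, start=1)
        ],
        source="intron",
        retained_columns=emap.retained_columns,
    )
    patterns = assign_patterns(
        sub, emap, presence_threshold=presence_threshold, naming="greek"
    )
    return emap, patterns


def combine_gene_patterns(
    exon_patterns: list[ElementPattern],
    intron_patterns: list[ElementPattern],
) -> list[GenePattern]:
    """Combine exon and intron pattern names into compound gene patterns.

    Both collections must cover the same sequence ids (the consensus entry
    is ignored); unmatched ids raise with the full list.
    """
    ex = {p.seq_id: p for p in exon_patterns if p.seq_id != CONSENSUS_NAME}
    it = {p.seq_id: p for p in intron_patterns if p.seq_id != CONSENSUS_NAME}
    missing = sorted(set(ex) ^ set(it))
    if missing:
        raise ValueError(f"unmatched sequence ids: {missing}")
    return [
        GenePattern(sid, ex[sid].pattern_name, it[sid].pattern_name)
        for sid in ex
    ]


def gene_pattern_tally(gene_patterns: list[GenePattern]) -> pd.DataFrame:
    """Count sequences per compound gene pattern, e.g. 'E-α' -> 11."""
    counts = pd.Series(
        [gp.combined_name for gp in gene_patterns]
    ).value_counts()
    return (
        counts.rename_axis("gene_pattern")
        .reset_index(name="n_sequences")
        .sort_values(["n_sequences", "gene_pattern"], ascending=[False, True])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def element_map_to_df(emap: ElementMap) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [e.element_id for e in emap.elements],
            "start_1based": [e.start + 1 for e in emap.elements],
            "end_1based": [e.end for e in emap.elements],
            "source": emap.source,
        }
    )


def element_map_from_df(df: pd.DataFrame) -> ElementMap:
    elements = [
        Element(str(r.element_id), int(r.start_1based) - 1, int(r.end_1based))
        for r in df.itertuples()
    ]
    source = str(df["source"].iloc[0]) if len(df) else "exon"
    return ElementMap(elements=elements, source=source)


def patterns_to_df(
    patterns: list[ElementPattern], emap: ElementMap
) -> pd.DataFrame:
    """Pattern table with a 0/1 presence column per element."""
    rows = []
    for p in patterns:
        row = {"seq_id": p.seq_id, "pattern_name": p.pattern_name}
        for e, pres in zip(emap.elements, p.presence):
            row[f"el_{e.element_id}"] = int(pres)
        rows.append(row)
    return pd.DataFrame(rows)


def patterns_from_df(df: pd.DataFrame) -> list[ElementPattern]:
    el_cols = [c for c in df.columns if c.startswith("el_")]
    return [
        ElementPattern(
            seq_id=str(r["seq_id"]),
            presence=tuple(bool(r[c]) for c in el_cols),
            pattern_name=str(r["pattern_name"]),
        )
        for _, r in df.iterrows()
    ]
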