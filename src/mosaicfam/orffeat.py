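"""ORF annotation, frameshift/premature-stop calls and polypeptide features.

Transcripts of the family carry a single ORF opened by an ATG in a Kozak
context (consensus ``CAGACATGG``) and closed by an in-frame stop.  A
minority of transcripts carry small indels or point mutations that shift
the reading frame or introduce early stop codons; these are detected by
comparing each aligned sequence against the alignment consensus and
translating in the running frame.  Deduced polypeptides are summarised by
molecular weight, isoelectric point, glycine-/histidine-rich regions,
poly-histidine runs, N-glycosylation sequons, RGD motifs and residue
censuses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .mosaic import ElementMap
from .seqio import GAP, MsAlignment, SequenceRecord

KOZAK = "CAGACATGG"  # ATG at offsets 5..7
KOZAK_MIN_SCORE = 7

CODON_TABLE = standard_dna_table.forward_table
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

# average (isotope-abundance-weighted) residue masses, Da
AVG_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

# side-chain / terminal pKa sets for the charge model
PKA_TABLES = {
    "emboss": {
        "nterm": 8.6, "cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    "bjellqvist": {
        "nterm": 7.5, "cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
}

SEQUON_RE = re.compile(r"N[^P][ST]")


class NoOrfError(ValueError):
    """No ATG with a downstream in-frame stop codon."""


@dataclass
class OrfAnnotation:
    seq_id: str
    orf_start: int  # 0-based nt, inclusive (the A of ATG)
    orf_end: int  # 0-based nt, exclusive (end of stop codon)
    kozak_ok: bool
    kozak_score: int = 0
    premature_stop_at: Optional[int] = None  # codon index within the ORF
    frameshift_events: list = None  # list of (nt position, indel_len % 3)
    status: str = "intact"  # {intact, truncated, missense}

    def __post_init__(self):
        if self.frameshift_events is None:
            self.frameshift_events = []

    @property
    def orf_len(self) -> int:
        return self.orf_end - self.orf_start


@dataclass
class ProteinFeatures:
    seq_id: str
    length_aa: int
    mw_da: float
    pi: float
    gly_rich_region: Optional[tuple[int, int]]
    his_rich_region: Optional[tuple[int, int]]
    polyhis_run: int
    n_sequons: int
    rgd_present: bool
    cys_count: int
    arg_fraction: float


def translate(dna: str) -> str:
    """Translate in frame 0 under the standard code; '*' marks stops.

    Codons containing gaps or ambiguity translate to 'X'; a trailing
    partial codon is ignored.
    """
    aa = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        if codon in STOP_CODONS:
            aa.append("*")
        else:
            aa.append(CODON_TABLE.get(codon, "X"))
    return "".join(aa)


def _kozak_score(seq: str, atg_pos: int) -> int:
    """Identity of the 9-nt context (5 nt upstream + ATG + 1 nt) to the
    Kozak consensus; positions falling off the sequence score 0."""
    score = 0
    for k in range(9):
        p = atg_pos - 5 + k
        if 0 <= p < len(seq) and seq[p] == KOZAK[k]:
            score += 1
    return score


def find_orf(rec: SequenceRecord) -> OrfAnnotation:
    """Locate the ORF of a cDNA: an ATG in Kozak context through the first
    in-frame stop codon.

    Policy: the first ATG whose context reaches the Kozak threshold (7/9
    identities to ``CAGACATGG``) and that has a downstream in-frame stop is
    chosen; if no ATG qualifies, the best-scoring ATG with an in-frame stop
    is used (ties broken by position).  Raises :class:`NoOrfError` when no
    ATG or no in-frame stop exists.
    """
    if rec.moltype != "dna":
        raise ValueError("find_orf requires a DNA record")
    seq = rec.ungapped()
    candidates = []  # (pos, score, stop_end)
    for m in re.finditer("ATG", seq):
        p = m.start()
        stop_end = None
        for i in range(p, len(seq) - 2, 3):
            if seq[i : i + 3] in STOP_CODONS:
                stop_end = i + 3
                break
        if stop_end is None:
            continue
        candidates.append((p, _kozak_score(seq, p), stop_end))
    if not candidates:
        raise NoOrfError(f"{rec.id}: no ATG with an in-frame stop codon")
    qualifying = [c for c in candidates if c[1] >= KOZAK_MIN_SCORE]
    if qualifying:
        p, score, stop_end = qualifying[0]
    else:
        p, score, stop_end = max(candidates, key=lambda c: (c[1], -c[0]))
    return OrfAnnotation(
        seq_id=rec.id,
        orf_start=p,
        orf_end=stop_end,
        kozak_ok=score >= KOZAK_MIN_SCORE,
        kozak_score=score,
    )


# ---------------------------------------------------------------------------
# Defect annotation against the alignment consensus
# ---------------------------------------------------------------------------

def _consensus_nongap(aln: MsAlignment) -> list[bool]:
    """Per column, whether the consensus state is non-gap (majority rule)."""
    n = aln.nrows
    return [
        sum(1 for r in aln.records if r.seq[j] != GAP) * 2 >= n
        for j in range(aln.ncols)
    ]


def annotate_defects(
    rec: SequenceRecord,
    aln: MsAlignment,
    emap: ElementMap,
    min_gap: int = 15,
    presence_threshold: float = 0.5,
) -> OrfAnnotation:
    """Call frameshifts and premature stops for one aligned ORF sequence.

    Indels are measured against the alignment consensus: maximal runs where
    the sequence and the consensus disagree on gap state.  Runs of length
    >= ``min_gap`` are element absences, not indels, and are ignored; any
    remaining run whose length is not a multiple of 3 is a frameshift.
    The ungapped sequence is translated in the running frame from the
    alignment start; a stop codon whose column lies upstream of the
    sequence's final present element is premature.  Status is ``truncated``
    when a premature stop exists, ``missense`` for a frameshift without a
    premature stop, else ``intact``.
    """
    if emap.retained_columns is not None:
        aln = aln.take_columns(emap.retained_columns)
    row = aln[rec.id]
    cons = _consensus_nongap(aln)
    s = row.seq
    ncols = aln.ncols

    # ungapped-position <-> column maps
    col_of_nt: list[int] = [j for j in range(ncols) if s[j] != GAP]
    nt_before_col = [0] * (ncols + 1)
    acc = 0
    for j in range(ncols):
        nt_before_col[j] = acc
        if s[j] != GAP:
            acc += 1
    nt_before_col[ncols] = acc

    # indel runs vs consensus
    frameshifts: list[tuple[int, int]] = []
    j = 0
    while j < ncols:
        is_del = s[j] == GAP and cons[j]
        is_ins = s[j] != GAP and not cons[j]
        if is_del or is_ins:
            k = j
            if is_del:
                while k < ncols and s[k] == GAP and cons[k]:
                    k += 1
            else:
                while k < ncols and s[k] != GAP and not cons[k]:
                    k += 1
            run = k - j
            if run < min_gap and run % 3 != 0:
                frameshifts.append((nt_before_col[j], run % 3))
            j = k
        else:
            j += 1

    # final present element of this sequence
    last_present_start = None
    for e in emap.elements:
        nongap = sum(1 for c in s[e.start : e.end] if c != GAP)
        if nongap >= presence_threshold * (e.end - e.start):
            last_present_start = e.start

    # translate in the running frame; find the first stop
    ungapped = row.ungapped()
    aa = translate(ungapped)
    premature = None
    stop_idx = aa.find("*")
    if stop_idx != -1 and last_present_start is not None:
        stop_col = col_of_nt[min(stop_idx * 3, len(col_of_nt) - 1)]
        if stop_col < last_present_start:
            premature = stop_idx

    if premature is not None:
        status = "truncated"
    elif frameshifts:
        status = "missense"
    else:
        status = "intact"
    return OrfAnnotation(
        seq_id=rec.id,
        orf_start=0,
        orf_end=len(ungapped),
        kozak_ok=True,
        premature_stop_at=premature,
        frameshift_events=frameshifts,
        status=status,
    )


# ---------------------------------------------------------------------------
# Polypeptide features
# ---------------------------------------------------------------------------

def molecular_weight(protein: str) -> float:
    """Average-mass MW: sum of residue masses plus one water."""
    try:
        return sum(AVG_RESIDUE_MASS[a] for a in protein) + WATER_MASS
    except KeyError as e:
        raise ValueError(f"unknown residue {e.args[0]!r}") from None


def net_charge(protein: str, ph: float, pka: dict) -> float:
    """Henderson-Hasselbalch net charge at the given pH."""
    pos = 1.0 / (1.0 + 10 ** (ph - pka["nterm"]))
    neg = 1.0 / (1.0 + 10 ** (pka["cterm"] - ph))
    for a in protein:
        if a in ("K", "R", "H"):
            pos += 1.0 / (1.0 + 10 ** (ph - pka[a]))
        elif a in ("D", "E", "C", "Y"):
            neg += 1.0 / (1.0 + 10 ** (pka[a] - ph))
    return pos - neg


def isoelectric_point(
    protein: str, pka_set: str = "emboss", tol: float = 1e-4
) -> float:
    """pI by bisection on the (strictly decreasing) net-charge function."""
    pka = PKA_TABLES[pka_set]
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _rich_region(
    protein: str, residue: str, window: int, enrich_fold: float
) -> Optional[tuple[int, int]]:
    """Longest maximal run of windows where the residue's frequency is at
    least enrich_fold times its whole-sequence frequency; returns the
    0-based half-open aa interval covered, or None."""
    L = len(protein)
    global_freq = protein.count(residue) / L
    if global_freq == 0:
        return None
    w = min(window, L)
    qualifying = []
    count = protein[:w].count(residue)
    for i in range(L - w + 1):
        if i > 0:
            count += (protein[i + w - 1] == residue) - (
                protein[i - 1] == residue
            )
        qualifying.append(count / w >= enrich_fold * global_freq)
    best = None
    i = 0
    while i < len(qualifying):
        if qualifying[i]:
            k = i
            while k < len(qualifying) and qualifying[k]:
                k += 1
            region = (i, k - 1 + w)
            if best is None or region[1] - region[0] > best[1] - best[0]:
                best = region
            i = k
        else:
            i += 1
    return best


def _longest_run(protein: str, residue: str) -> int:
    best = run = 0
    for a in protein:
        run = run + 1 if a == residue else 0
        best = max(best, run)
    return best


def protein_features(
    prot: SequenceRecord, window: int = 30, enrich_fold: float = 2.0,
    pka_set: str = "emboss",
) -> ProteinFeatures:
    """Composition features of one deduced polypeptide.

    Sequons are N-{P}-[ST] motifs (overlapping matches counted); the RGD
    integrin-binding motif is an exact substring test.
    """
    seq = prot.ungapped().rstrip("*")
    if not seq:
        raise ValueError(f"{prot.id}: empty protein sequence")
    n_sequons = 0
    for i in range(len(seq) - 2):
        if SEQUON_RE.match(seq, i):
            n_sequons += 1
    return ProteinFeatures(
        seq_id=prot.id,
        length_aa=len(seq),
        mw_da=molecular_weight(seq),
        pi=isoelectric_point(seq, pka_set=pka_set),
        gly_rich_region=_rich_region(seq, "G", window, enrich_fold),
        his_rich_region=_rich_region(seq, "H", window, enrich_fold),
        polyhis_run=_longest_run(seq, "H"),
        n_sequons=n_sequons,
        rgd_present="RGD" in seq,
        cys_count=seq.count("C"),
        arg_fraction=seq.count("R") / len(seq),
    )


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def orf_annotations_to_df(anns: list[OrfAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [a.seq_id for a in anns],
            "orf_start_1based": [a.orf_start + 1 for a in anns],
            "orf_end_1based": [a.orf_end for a in anns],
            "kozak_ok": [int(a.kozak_ok) for a in anns],
            "premature_stop_codon": [
                "" if a.premature_stop_at is None else a.premature_stop_at
                for a in anns
            ],
            "n_frameshifts": [len(a.frameshift_events) for a in anns],
            "status": [a.status for a in anns],
        }
    )


def protein_features_to_df(feats: list[ProteinFeatures]) -> pd.DataFrame:
    def _iv(iv):
        return "" if iv is None else f"{iv[0] + 1}-{iv[1]}"

    return pd.DataFrame(
        {
            "seq_id": [f.seq_id for f in feats],
            "length_aa": [f.length_aa for f in feats],
            "mw_da": [round(f.mw_da, 2) for f in feats],
            "pi": [round(f.pi, 3) for f in feats],
            "gly_rich_1based": [_iv(f.gly_rich_region) for f in feats],
            "his_rich_1based": [_iv(f.his_rich_region) for f in feats],
            "polyhis_run": [f.polyhis_run for f in feats],
            "n_sequons": [f.n_sequons for f in feats],
            "rgd_present": [int(f.rgd_present) for f in feats],
            "cys_count": [f.cys_count for f in feats],
            "arg_fraction": [round(f.arg_fraction, 4) for f in feats],
        }
    )
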