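"""Polymorphism discovery and classification on an aligned allele panel.

Every allele is globally aligned to one reference allele (by convention the first
red-flesh allele by sorted id).  Substitution columns become SNPs; gap runs are
merged into single left-normalized InDel events; length variation that falls
inside a microsatellite locus detected on the reference is reported as SSR
repeat-count variation rather than as an InDel.  Each variant is then classified
by gene region (promoter / exon_i / intron_i), by group specificity
(diagnostic between red- and white-flesh alleles, subtype-specific, or
nondiagnostic) and by coding effect.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Seq import Seq

from .io_core import (
    AlleleRecord,
    CoordinateError,
    GeneModel,
    convert_coordinate,
    group_of,
    invert_coordinate,
)

logger = logging.getLogger(__name__)

SPECIFICITY_CLASSES = ("Rf_vs_Wf", "WsWf_specific", "RsWf_specific")
REGION_CLASSES = ("Promoter", "Exon", "Intron")
KINDS = ("SNP", "InDel", "SSR")


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignParams:
    """Global affine-gap alignment scores.

    A gap of length L scores ``gap_open + L * gap_extend`` (so a 1-nt gap costs
    ``gap_open + gap_extend``).  The defaults make a substitution (score swing
    ``match - mismatch`` = 5) cheaper than any gap, so isolated differences are
    called as SNPs rather than paired indels.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -8.0
    gap_extend: float = -1.0


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # Biopython charges open_gap_score for the first gap base, extend for the rest.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def align_pair(reference: str, query: str, params: AlignParams | None = None) -> Align.Alignment:
    """Global affine-gap alignment of ``query`` against ``reference``.

    Ties are broken deterministically by taking the aligner's first reported
    alignment; indel placement is subsequently left-normalized during variant
    calling, so reported positions do not depend on the tie chosen here.
    """
    if not reference or not query:
        raise ValueError("align_pair requires two non-empty sequences")
    aligner = _make_aligner(params or AlignParams())
    return aligner.align(reference, query)[0]


@dataclass(frozen=True)
class _IndelEvent:
    op: str  # 'ins' | 'del'
    pos: int  # 1-based reference position (left-normalized); for 'ins' the
    # reference base before which the insertion sits
    seq: str  # inserted or deleted sequence


def left_normalize(reference: str, pos: int, op: str, seq: str) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement (VCF-style).

    ``pos`` is 1-based: for deletions the first deleted reference base, for
    insertions the reference base before which the insertion occurs.
    """
    while pos > 1 and seq and seq[-1] == reference[pos - 2]:
        seq = reference[pos - 2] + seq[:-1]
        pos -= 1
    return pos, seq


def _alignment_blocks(alignment: Align.Alignment) -> np.ndarray:
    blocks = np.asarray(alignment.aligned)
    return blocks  # shape (2, nblocks, 2); 0-based half-open (ref row 0, query row 1)


def extract_events(
    alignment: Align.Alignment, reference: str, query: str
) -> tuple[dict[int, str], list[_IndelEvent]]:
    """Substitution columns and merged, left-normalized indel events.

    Returns ``(snps, indels)`` where ``snps`` maps 1-based reference position to
    the query base at that column (including 'N').
    """
    blocks = _alignment_blocks(alignment)
    ref_blocks, q_blocks = blocks[0], blocks[1]
    snps: dict[int, str] = {}
    indels: list[_IndelEvent] = []

    rb = np.frombuffer(reference.encode(), dtype=np.uint8)
    qb = np.frombuffer(query.encode(), dtype=np.uint8)

    def add_gap(prev_r: int, prev_q: int, next_r: int, next_q: int) -> None:
        rgap, qgap = next_r - prev_r, next_q - prev_q
        if rgap > 0:  # deletion in query
            pos, seq = left_normalize(reference, prev_r + 1, "del", reference[prev_r:next_r])
            indels.append(_IndelEvent("del", pos, seq))
        if qgap > 0:  # insertion in query (before reference base next_r+1... prev_r+1)
            pos, seq = left_normalize(reference, prev_r + 1, "ins", query[prev_q:next_q])
            indels.append(_IndelEvent("ins", pos, seq))

    if len(ref_blocks):
        if ref_blocks[0][0] > 0 or q_blocks[0][0] > 0:
            add_gap(0, 0, ref_blocks[0][0], q_blocks[0][0])
        for k in range(len(ref_blocks)):
            rs, re = ref_blocks[k]
            qs, qe = q_blocks[k]
            seg_ne = rb[rs:re] != qb[qs:qe]
            for off in np.nonzero(seg_ne)[0]:
                snps[int(rs + off + 1)] = query[qs + off]
            if k + 1 < len(ref_blocks):
                add_gap(re, qe, ref_blocks[k + 1][0], q_blocks[k + 1][0])
        if ref_blocks[-1][1] < len(reference) or q_blocks[-1][1] < len(query):
            add_gap(ref_blocks[-1][1], q_blocks[-1][1], len(reference), len(query))
    return snps, indels


# ---------------------------------------------------------------------------
# panel alignment container
# ---------------------------------------------------------------------------


def choose_reference(panel: Sequence[AlleleRecord]) -> AlleleRecord:
    """First red-flesh allele by sorted id; falls back to first allele overall."""
    rf = sorted((a for a in panel if group_of(a) == "Rf"), key=lambda a: a.allele_id)
    if rf:
        return rf[0]
    return sorted(panel, key=lambda a: a.allele_id)[0]


class PanelAlignment:
    """All panel alleles aligned to a common reference allele.

    Caches per-allele substitution/indel events, deleted intervals and a
    reference-column base matrix, which the variant caller, the primer designer
    and the distance-matrix builder all share.
    """

    def __init__(
        self,
        panel: Sequence[AlleleRecord],
        reference_id: str | None = None,
        params: AlignParams | None = None,
    ) -> None:
        if not panel:
            raise ValueError("empty panel")
        by_id = {a.allele_id: a for a in panel}
        if len(by_id) != len(panel):
            raise ValueError("duplicate allele ids in panel")
        if reference_id is None:
            reference_id = choose_reference(panel).allele_id
        if reference_id not in by_id:
            raise ValueError(f"reference allele {reference_id!r} not in panel")
        self.panel = list(panel)
        self.records = by_id
        self.reference_id = reference_id
        self.reference = by_id[reference_id].sequence
        self.params = params or AlignParams()

        self.snps: dict[str, dict[int, str]] = {}
        self.indels: dict[str, list[_IndelEvent]] = {}
        self._blocks: dict[str, np.ndarray] = {}
        for rec in self.panel:
            if rec.allele_id == reference_id:
                self.snps[rec.allele_id] = {}
                self.indels[rec.allele_id] = []
                n = len(self.reference)
                self._blocks[rec.allele_id] = np.array([[[0, n]], [[0, n]]])
                continue
            aln = align_pair(self.reference, rec.sequence, self.params)
            self._blocks[rec.allele_id] = _alignment_blocks(aln)
            s, d = extract_events(aln, self.reference, rec.sequence)
            self.snps[rec.allele_id] = s
            self.indels[rec.allele_id] = d

    # -- coordinate mapping -------------------------------------------------

    def to_allele(self, allele_id: str, ref_pos: int) -> int | None:
        """Map a 1-based reference position to the allele's own coordinates.

        Returns ``None`` if the base is deleted in that allele.
        """
        blocks = self._blocks[allele_id]
        starts = blocks[0][:, 0]
        k = bisect_right(starts.tolist(), ref_pos - 1) - 1
        if k < 0:
            return None
        rs, re = blocks[0][k]
        qs, _qe = blocks[1][k]
        if not (rs <= ref_pos - 1 < re):
            return None
        return int(qs + (ref_pos - 1 - rs) + 1)

    def deleted_intervals(self, allele_id: str) -> list[tuple[int, int]]:
        return [
            (e.pos, e.pos + len(e.seq) - 1)
            for e in self.indels[allele_id]
            if e.op == "del"
        ]

    def base_matrix(self) -> tuple[list[str], np.ndarray]:
        """(allele ids, matrix) of per-reference-column bases; 0 where deleted."""
        ids = sorted(self.records)
        n = len(self.reference)
        mat = np.zeros((len(ids), n), dtype=np.uint8)
        refb = np.frombuffer(self.reference.encode(), dtype=np.uint8)
        for i, aid in enumerate(ids):
            row = refb.copy()
            for pos, base in self.snps[aid].items():
                row[pos - 1] = ord(base)
            for s, e in self.deleted_intervals(aid):
                row[s - 1 : e] = 0
            mat[i] = row
        return ids, mat


# ---------------------------------------------------------------------------
# SSR detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SSRLocus:
    unit: str  # canonical (lexicographically smallest rotation)
    start: int  # 1-based position of the first repeat base
    repeats: int  # full repeat count on this sequence

    @property
    def length(self) -> int:
        return len(self.unit) * self.repeats

    @property
    def end(self) -> int:
        return self.start + self.length - 1


def canonical_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def _is_primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def detect_ssr_loci(
    sequence: str,
    min_unit: int = 1,
    max_unit: int = 6,
    min_repeats: int = 4,
    min_length: int = 8,
) -> list[SSRLocus]:
    """Maximal non-overlapping tandem repeat loci.

    A locus is a maximal run of a primitive unit repeated at least ``min_repeats``
    full times over at least ``min_length`` bases (partial trailing repeats are
    trimmed).  Overlaps between candidate loci are resolved in favour of the
    longer locus, ties broken by leftmost start, then shortest unit.
    """
    if min(min_unit, max_unit, min_repeats, min_length) <= 0:
        raise ValueError("SSR thresholds must be positive")
    n = len(sequence)
    candidates: list[SSRLocus] = []
    for u in range(min_unit, max_unit + 1):
        j = u
        while j < n:
            if sequence[j] == sequence[j - u] and sequence[j] in "ACGT":
                a = j
                while j < n and sequence[j] == sequence[j - u] and sequence[j] in "ACGT":
                    j += 1
                total = (j - a) + u
                start0 = a - u
                repeats = total // u
                unit = sequence[start0 : start0 + u]
                if (
                    repeats >= min_repeats
                    and repeats * u >= min_length
                    and set(unit) <= set("ACGT")
                    and _is_primitive(unit)
                ):
                    candidates.append(
                        SSRLocus(canonical_rotation(unit), start0 + 1, repeats)
                    )
            else:
                j += 1
    return resolve_ssr_overlaps(candidates)


def resolve_ssr_overlaps(candidates: Iterable[SSRLocus]) -> list[SSRLocus]:
    chosen: list[SSRLocus] = []
    for loc in sorted(candidates, key=lambda l: (-l.length, l.start, len(l.unit))):
        if all(loc.end < c.start or loc.start > c.end for c in chosen):
            chosen.append(loc)
    return sorted(chosen, key=lambda l: l.start)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


@dataclass
class Variant:
    """One polymorphism keyed to ATG-relative reference coordinates.

    ``states`` maps every panel allele id to its state at the site: a base for
    SNPs, ``'ref'`` / ``'ins:SEQ'`` / ``'del:SEQ'`` for InDels, an integer repeat
    count for SSRs, or ``None`` when the allele carries no information there
    (N base or deleted region).
    """

    kind: str  # SNP | InDel | SSR
    position: int  # ATG-relative, leftmost affected base
    genomic_pos: int  # 1-based on the reference allele
    region: str  # promoter | exon_i | intron_i
    ref_state: object
    states: dict[str, object]
    length: int
    specificity: str = "nondiagnostic"
    unit: str | None = None
    coding_effect: str | None = None
    ambiguous: bool = False

    @property
    def region_class(self) -> str:
        return self.region.split("_")[0].capitalize()


def classify_specificity(
    states: Mapping[str, object], allele_info: Mapping[str, tuple[str | None, str | None]]
) -> str:
    """Classify a site from its per-allele states.

    Diagnostic (``Rf_vs_Wf``) iff all red-flesh alleles share one state and all
    white-flesh alleles share a different one.  ``WsWf_specific`` (analogously
    ``RsWf_specific``) iff that subtype's alleles share a state that differs from
    the single state shared by every other allele.  Alleles with missing states
    are excluded from the vote.
    """
    known = {a: s for a, s in states.items() if s is not None}
    dropped = set(states) - set(known)
    if dropped:
        logger.debug("specificity vote excludes alleles with missing state: %s", sorted(dropped))

    def states_of(pred) -> set:
        return {s for a, s in known.items() if pred(allele_info.get(a, (None, None)))}

    rf = states_of(lambda gi: gi[0] == "Rf")
    wf = states_of(lambda gi: gi[0] == "Wf")
    if rf and wf and len(rf) == 1 and len(wf) == 1 and rf != wf:
        return "Rf_vs_Wf"
    for subtype in ("WsWf", "RsWf"):
        sub = states_of(lambda gi, st=subtype: gi[1] == st)
        rest = states_of(lambda gi, st=subtype: gi[1] is not None and gi[1] != st)
        if sub and rest and len(sub) == 1 and len(rest) == 1 and sub != rest:
            return f"{subtype}_specific"
    return "nondiagnostic"


def annotate_coding_effect(variant: Variant, model: GeneModel, reference: str) -> str:
    """synonymous / nonsynonymous / frameshift / in_frame_indel / noncoding."""
    cds = model.cds_positions()
    cds_index = {p: i for i, p in enumerate(cds)}
    pos = variant.genomic_pos
    lo, hi = model.span
    if not (lo <= pos <= hi):
        raise CoordinateError(f"variant at genomic {pos} outside model span")

    if variant.kind == "SNP":
        if pos not in cds_index:
            return "noncoding"
        alt = next(
            (s for s in variant.states.values() if s is not None and s != variant.ref_state),
            None,
        )
        if alt is None:
            return "synonymous"
        i = cds_index[pos]
        codon_start = (i // 3) * 3
        codon_pos = [cds[codon_start + k] for k in range(3) if codon_start + k < len(cds)]
        if len(codon_pos) < 3:
            return "noncoding"  # trailing partial codon
        ref_codon = "".join(reference[p - 1] for p in codon_pos)
        alt_codon = "".join(
            str(alt) if p == pos else reference[p - 1] for p in codon_pos
        )
        same = Seq(ref_codon).translate() == Seq(alt_codon).translate()
        return "synonymous" if same else "nonsynonymous"

    # length-changing variants
    if variant.kind == "SSR":
        span = range(pos, pos + len(variant.unit or "") * int(variant.ref_state or 1))
        delta = variant.length
    else:
        span = range(pos, pos + variant.length) if "del" in _indel_ops(variant) else range(
            pos - 1, pos + 1
        )
        delta = variant.length
    inside = [p for p in span if p in cds_index]
    if not inside or len(inside) < len(list(span)):
        # not strictly inside the CDS (intron, promoter, UTR, or junction-spanning)
        if not inside:
            return "noncoding"
    return "in_frame_indel" if delta % 3 == 0 else "frameshift"


def _indel_ops(variant: Variant) -> set[str]:
    return {
        str(s).split(":")[0]
        for s in variant.states.values()
        if isinstance(s, str) and s not in ("ref",)
    }


# ---------------------------------------------------------------------------
# variant calling
# ---------------------------------------------------------------------------


def _ssr_locus_for(
    event: _IndelEvent, loci: Sequence[SSRLocus]
) -> tuple[SSRLocus | None, bool]:
    """Match an indel event to an SSR locus.

    Returns (locus, inside).  ``inside`` is False for events that overlap a locus
    boundary or whose sequence is not whole repeats of the locus unit; those are
    flagged ambiguous rather than silently converted or dropped.
    """
    L = len(event.seq)
    for loc in loci:
        u = len(loc.unit)
        if event.op == "ins":
            overlap = loc.start <= event.pos <= loc.end + 1
        else:
            overlap = not (event.pos + L - 1 < loc.start or event.pos > loc.end)
        if not overlap:
            continue
        whole = L % u == 0 and event.seq == event.seq[:u] * (L // u)
        unit_ok = whole and canonical_rotation(event.seq[:u]) == loc.unit
        if event.op == "del":
            contained = event.pos >= loc.start and event.pos + L - 1 <= loc.end
        else:
            contained = True
        return loc, bool(unit_ok and contained)
    return None, False


def call_variants(
    panel: Sequence[AlleleRecord] | PanelAlignment,
    model: GeneModel,
    reference_id: str | None = None,
    params: AlignParams | None = None,
    anchor: str = "atg",
    ssr_kwargs: Mapping[str, int] | None = None,
) -> list[Variant]:
    """Call and classify SNPs, InDels and SSR repeat-count variants on a panel."""
    pa = (
        panel
        if isinstance(panel, PanelAlignment)
        else PanelAlignment(panel, reference_id=reference_id, params=params)
    )
    ref = pa.reference
    allele_ids = sorted(pa.records)
    allele_info = {
        aid: (group_of(pa.records[aid]), pa.records[aid].subtype) for aid in allele_ids
    }
    loci = detect_ssr_loci(ref, **dict(ssr_kwargs or {}))

    # Partition indel events first: length variation inside an SSR locus becomes
    # repeat-count variation, the rest stay InDels.  Only the remaining deletions
    # blank out an allele's state at overlapped sites.
    ssr_delta: dict[SSRLocus, dict[str, int]] = {}
    indel_groups: dict[tuple[int, str, str], dict[str, str]] = {}
    ambiguous_keys: set[tuple[int, str, str]] = set()
    deleted: dict[str, list[tuple[int, int]]] = {aid: [] for aid in allele_ids}
    for aid in allele_ids:
        for ev in pa.indels[aid]:
            loc, inside = _ssr_locus_for(ev, loci)
            if loc is not None and inside:
                delta = (len(ev.seq) // len(loc.unit)) * (1 if ev.op == "ins" else -1)
                ssr_delta.setdefault(loc, {})[aid] = (
                    ssr_delta.get(loc, {}).get(aid, 0) + delta
                )
                continue
            key = (int(ev.pos), ev.op, ev.seq)
            indel_groups.setdefault(key, {})[aid] = f"{ev.op}:{ev.seq}"
            if ev.op == "del":
                deleted[aid].append((int(ev.pos), int(ev.pos) + len(ev.seq) - 1))
            if loc is not None and not inside:
                ambiguous_keys.add(key)
                logger.warning(
                    "indel at %d overlaps SSR locus %s(%d) boundary: flagged ambiguous",
                    ev.pos,
                    loc.unit,
                    loc.start,
                )

    def missing_at(aid: str, pos: int) -> bool:
        return any(s <= pos <= e for s, e in deleted[aid])

    variants: list[Variant] = []

    # ---- SNPs -------------------------------------------------------------
    snp_positions = sorted({p for aid in allele_ids for p in pa.snps[aid]})
    for pos in snp_positions:
        ref_base = ref[pos - 1]
        if ref_base == "N":
            continue
        states: dict[str, object] = {}
        for aid in allele_ids:
            if missing_at(aid, pos):
                states[aid] = None
                continue
            base = pa.snps[aid].get(pos, ref_base)
            states[aid] = None if base == "N" else base
        observed = {s for s in states.values() if s is not None}
        if len(observed) < 2:
            continue  # only N-carriers differed
        variants.append(
            Variant(
                kind="SNP",
                position=convert_coordinate(pos, anchor, model),
                genomic_pos=pos,
                region=model.region_name(pos),
                ref_state=ref_base,
                states=states,
                length=1,
            )
        )

    # ---- InDels and SSR repeat variation ----------------------------------
    for (pos, op, seq), carriers in sorted(indel_groups.items()):
        states = {}
        for aid in allele_ids:
            if aid in carriers:
                states[aid] = carriers[aid]
            elif missing_at(aid, pos):
                states[aid] = None
            else:
                states[aid] = "ref"
        variants.append(
            Variant(
                kind="InDel",
                position=convert_coordinate(pos, anchor, model),
                genomic_pos=pos,
                region=model.region_name(pos),
                ref_state="ref",
                states=states,
                length=len(seq),
                ambiguous=(pos, op, seq) in ambiguous_keys,
            )
        )

    for loc in sorted(ssr_delta, key=lambda l: l.start):
        deltas = ssr_delta[loc]
        states = {}
        for aid in allele_ids:
            if missing_at(aid, loc.start):
                states[aid] = None
            else:
                states[aid] = loc.repeats + deltas.get(aid, 0)
        counts = {s for s in states.values() if s is not None}
        if len(counts) < 2:
            continue
        lo_c, hi_c = min(counts), max(counts)
        variants.append(
            Variant(
                kind="SSR",
                position=convert_coordinate(loc.start, anchor, model),
                genomic_pos=loc.start,
                region=model.region_name(loc.start),
                ref_state=loc.repeats,
                states=states,
                length=(hi_c - lo_c) * len(loc.unit),
                unit=loc.unit,
            )
        )

    # ---- classification & annotation --------------------------------------
    for v in variants:
        v.specificity = classify_specificity(v.states, allele_info)
        v.coding_effect = annotate_coding_effect(v, model, ref)
    variants.sort(key=lambda v: (v.genomic_pos, v.kind))
    return variants


# ---------------------------------------------------------------------------
# summary matrix (Promoter/Exon/Intron x kind x specificity class)
# ---------------------------------------------------------------------------


def summarize_matrix(variants: Sequence[Variant]) -> pd.DataFrame:
    """Counts by region class, variant kind, and specificity class, plus a Total
    row.  Nondiagnostic and ambiguous variants are excluded."""
    columns = pd.MultiIndex.from_product(
        [SPECIFICITY_CLASSES, KINDS], names=["specificity", "kind"]
    )
    mat = pd.DataFrame(
        0, index=list(REGION_CLASSES) + ["Total"], columns=columns, dtype=int
    )
    for v in variants:
        if v.specificity not in SPECIFICITY_CLASSES or v.ambiguous:
            continue
        mat.loc[v.region_class, (v.specificity, v.kind)] += 1
    mat.loc["Total"] = mat.loc[list(REGION_CLASSES)].sum(axis=0)
    return mat


def variants_to_frame(variants: Sequence[Variant]) -> pd.DataFrame:
    rows = []
    for v in variants:
        rows.append(
            {
                "kind": v.kind,
                "position_atg": v.position,
                "region": v.region,
                "ref_state": v.ref_state,
                "length": v.length,
                "unit": v.unit or "",
                "specificity": v.specificity,
                "coding_effect": v.coding_effect or "",
                "ambiguous": int(v.ambiguous),
                "states": ";".join(
                    f"{aid}={'.' if s is None else s}" for aid, s in sorted(v.states.items())
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kind",
            "position_atg",
            "region",
            "ref_state",
            "length",
            "unit",
            "specificity",
            "coding_effect",
            "ambiguous",
            "states",
        ],
    )
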