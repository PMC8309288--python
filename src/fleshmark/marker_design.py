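"""Design of the four flesh-colour marker types from classified variants.

Two discrimination modes are produced:

* codominant length markers (ID-P over the 14-nt promoter insertion, SSR-P over
  the diagnostic microsatellite) — one conserved primer pair flanking the
  length polymorphism, so allele classes separate by band size and
  heterozygotes show both bands;
* dominant allele-specific pairs (PS-P over promoter SNPs, WD/AD-P over the
  intron-5 InDel plus exon-6 SNPs) — an Rf-specific and a Wf-specific pair,
  each matching its own haplotype perfectly and mismatching the other group at
  the 3'-terminal base of at least one primer.

Candidate primers are ranked by |Tm - 60 degC|, then |GC - 50%|, then leftmost
position, and every accepted design is verified by exact in-silico PCR against
the whole panel: length-mode primers must amplify every allele exactly once;
allele-specific pairs must amplify every own-group allele and no other-group
allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp

from .io_core import AlleleRecord, GeneModel, group_of, revcomp
from .variant_analysis import PanelAlignment, Variant

logger = logging.getLogger(__name__)

MARKER_NAMES = ("PS-P", "ID-P", "SSR-P", "WD/AD-P")


class DesignError(RuntimeError):
    """No primer set satisfying the constraints could be found."""


@dataclass(frozen=True)
class PrimerConstraints:
    """Physical constraints for candidate primers.

    The Tm window brackets the validation protocol's annealing temperature
    (62 degC); amplicons must resolve on an agarose gel, hence the size range.
    The GC band is acceptance, not preference (ranking already favours 50%):
    allele-specific primers are pinned to their diagnostic site, so on an
    AT-rich template a tight GC band would reject every anchored candidate.
    """

    length: tuple[int, int] = (18, 24)
    tm: tuple[float, float] = (55.0, 65.0)
    gc: tuple[float, float] = (0.20, 0.80)
    product: tuple[int, int] = (100, 1200)
    max_run: int = 4
    search_span: int = 160  # how far from the target to look for conserved windows

    def __post_init__(self) -> None:
        for name in ("length", "tm", "gc", "product"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range is empty: {lo}..{hi}")


@dataclass(frozen=True)
class Primer:
    sequence: str
    orientation: str  # fw | rv
    ref_start: int  # 1-based on the reference allele (approximate for indels)
    ref_end: int

    @property
    def tm(self) -> float:
        return compute_tm(self.sequence)

    @property
    def gc(self) -> float:
        return gc_fraction(self.sequence)


@dataclass
class PrimerSet:
    marker_name: str
    mode: str  # codominant_length | dominant_allele_specific_pair
    pairs: dict[str, tuple[Primer, Primer]]  # 'band' or group name -> (fw, rv)
    expected_sizes: dict[str, int]  # allele class -> product size (nt)
    anchors: tuple[int, ...] = ()  # ATG-relative anchored diagnostic sites
    description: str = ""


@dataclass(frozen=True)
class DesignFailure:
    marker_name: str
    reason: str


# ---------------------------------------------------------------------------
# primer physics
# ---------------------------------------------------------------------------


def compute_tm(primer: str, method: str = "wallace") -> float:
    """Melting temperature: Wallace rule 2(A+T) + 4(G+C) by default, or the
    nearest-neighbor thermodynamic model (``method='nn'``)."""
    if len(primer) < 8:
        raise ValueError("primer too short for a meaningful Tm (need >= 8 nt)")
    bad = set(primer) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous bases in primer: {sorted(bad)}")
    if method == "wallace":
        at = primer.count("A") + primer.count("T")
        gc = primer.count("G") + primer.count("C")
        return 2.0 * at + 4.0 * gc
    if method == "nn":
        return float(MeltingTemp.Tm_NN(primer))
    raise ValueError(f"unknown Tm method {method!r}")


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_mononucleotide_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _passes(seq: str, c: PrimerConstraints) -> bool:
    return (
        c.length[0] <= len(seq) <= c.length[1]
        and c.tm[0] <= compute_tm(seq) <= c.tm[1]
        and c.gc[0] <= gc_fraction(seq) <= c.gc[1]
        and max_mononucleotide_run(seq) <= c.max_run
        and not set(seq) - set("ACGT")
    )


def _rank_key(seq: str, position: int) -> tuple:
    return (abs(compute_tm(seq) - 60.0), abs(gc_fraction(seq) - 0.5), position)


# ---------------------------------------------------------------------------
# polymorphism mask
# ---------------------------------------------------------------------------


def polymorphic_mask(variants: Sequence[Variant], ref_len: int) -> np.ndarray:
    """Boolean array (1-based positions shifted to 0-based) of reference bases
    that vary anywhere in the panel, with 1 nt of safety margin."""
    mask = np.zeros(ref_len, dtype=bool)

    def block(lo: int, hi: int) -> None:
        mask[max(0, lo - 1) : min(ref_len, hi)] = True

    for v in variants:
        p = v.genomic_pos
        if v.kind == "SNP":
            block(p, p)
        elif v.kind == "SSR":
            span = len(v.unit or "") * int(v.ref_state or 1)
            block(p - 1, p + span)
        else:
            ops = {
                str(s).split(":")[0]
                for s in v.states.values()
                if isinstance(s, str) and s != "ref"
            }
            if "del" in ops:
                block(p - 1, p + v.length)
            else:
                block(p - 1, p + 1)
    return mask


def _conserved_windows(
    reference: str,
    mask: np.ndarray,
    region: tuple[int, int],
    c: PrimerConstraints,
    orientation: str,
) -> list[Primer]:
    """Constraint-passing primers fully inside ``region`` (1-based inclusive)
    whose footprint is conserved; ranked."""
    lo, hi = max(1, region[0]), min(len(reference), region[1])
    out: list[Primer] = []
    for start in range(lo, hi + 1):
        for L in range(c.length[0], c.length[1] + 1):
            end = start + L - 1
            if end > hi:
                break
            if mask[start - 1 : end].any():
                continue
            window = reference[start - 1 : end]
            seq = window if orientation == "fw" else revcomp(window)
            if _passes(seq, c):
                out.append(Primer(seq, orientation, start, end))
    out.sort(key=lambda p: _rank_key(p.sequence, p.ref_start))
    return out


# ---------------------------------------------------------------------------
# class representatives and verification
# ---------------------------------------------------------------------------


def _group_alleles(panel: Sequence[AlleleRecord]) -> dict[str, list[AlleleRecord]]:
    groups: dict[str, list[AlleleRecord]] = {"Rf": [], "Wf": []}
    for a in panel:
        g = group_of(a)
        if g in groups:
            groups[g].append(a)
    for g in groups:
        groups[g].sort(key=lambda a: a.allele_id)
    return groups


def _majority_size(sizes: Sequence[int]) -> int | None:
    if not sizes:
        return None
    vals, counts = np.unique(np.asarray(sizes), return_counts=True)
    return int(vals[np.argmax(counts)])


def _products(fw: Primer, rv: Primer, template: str, c: PrimerConstraints) -> list[int]:
    from .insilico_genotyping import simulate_pcr  # local import; module depends on us

    return [a.size for a in simulate_pcr(fw.sequence, rv.sequence, template, c.product)]


# ---------------------------------------------------------------------------
# length markers (codominant)
# ---------------------------------------------------------------------------


def target_footprint(target: Variant) -> tuple[int, int]:
    p = target.genomic_pos
    if target.kind == "SSR":
        return p, p + len(target.unit or "") * int(target.ref_state or 1) - 1
    ops = {
        str(s).split(":")[0]
        for s in target.states.values()
        if isinstance(s, str) and s != "ref"
    }
    if "del" in ops:
        return p, p + target.length - 1
    return p - 1, p  # insertion between the two flanking bases


def expected_length_difference(target: Variant) -> int:
    if target.kind == "SSR":
        counts = [int(s) for s in target.states.values() if s is not None]
        return (max(counts) - min(counts)) * len(target.unit or "")
    return target.length


def design_length_marker(
    target: Variant,
    pa: PanelAlignment,
    constraints: PrimerConstraints | None = None,
    mask_variants: Sequence[Variant] | None = None,
    marker_name: str = "length-marker",
) -> PrimerSet:
    """Codominant marker: conserved primers flanking an InDel or SSR target."""
    if target.kind not in ("InDel", "SSR"):
        raise DesignError(f"{marker_name}: length markers need an InDel or SSR target")
    c = constraints or PrimerConstraints()
    mask = polymorphic_mask(mask_variants if mask_variants is not None else [target],
                            len(pa.reference))
    fs, fe = target_footprint(target)
    fw_cands = _conserved_windows(
        pa.reference, mask, (fs - c.search_span, fs - 1), c, "fw"
    )
    rv_cands = _conserved_windows(
        pa.reference, mask, (fe + 1, fe + c.search_span), c, "rv"
    )
    if not fw_cands or not rv_cands:
        raise DesignError(
            f"{marker_name}: no conserved constraint-passing primer window "
            f"{'upstream' if not fw_cands else 'downstream'} of the target"
        )
    groups = _group_alleles(pa.panel)
    want_diff = expected_length_difference(target)
    for fw in fw_cands[:40]:
        for rv in rv_cands[:40]:
            ref_size = rv.ref_end - fw.ref_start + 1
            if not (c.product[0] <= ref_size <= c.product[1]):
                continue
            per_allele: dict[str, list[int]] = {}
            ok = True
            for al in pa.panel:
                sizes = _products(fw, rv, al.sequence, c)
                if len(sizes) != 1:
                    ok = False
                    break
                per_allele[al.allele_id] = sizes
            if not ok:
                continue
            expected: dict[str, int] = {}
            for g, members in groups.items():
                size = _majority_size(
                    [per_allele[a.allele_id][0] for a in members if a.allele_id in per_allele]
                )
                if size is not None:
                    expected[g] = size
            if len(expected) == 2 and abs(expected["Rf"] - expected["Wf"]) != want_diff:
                continue
            return PrimerSet(
                marker_name=marker_name,
                mode="codominant_length",
                pairs={"band": (fw, rv)},
                expected_sizes=expected,
                anchors=(target.position,),
                description=f"{target.kind} at ATG{target.position:+d}, "
                f"length difference {want_diff} nt",
            )
    raise DesignError(f"{marker_name}: no primer pair with a valid product on every allele")


# ---------------------------------------------------------------------------
# allele-specific pairs (dominant)
# ---------------------------------------------------------------------------


def _anchor_end_candidates(
    anchor: Variant, rep_id: str, pa: PanelAlignment
) -> list[int]:
    """Candidate 3'-end positions (allele coordinates) at/around a diagnostic
    site.  For SNPs this is the site itself; for InDels, positions across the
    junction so the primer terminus discriminates presence/absence."""
    if anchor.kind == "SNP":
        q = pa.to_allele(rep_id, anchor.genomic_pos)
        return [q] if q is not None else []
    lo = anchor.genomic_pos - 1
    hi = anchor.genomic_pos + anchor.length + 1
    mapped = [pa.to_allele(rep_id, p) for p in range(lo, hi + 1)]
    return sorted({m for m in mapped if m is not None})


def _forward_candidates(
    anchor: Variant, rep: AlleleRecord, pa: PanelAlignment, c: PrimerConstraints
) -> list[Primer]:
    out = []
    for end in _anchor_end_candidates(anchor, rep.allele_id, pa):
        for L in range(c.length[0], c.length[1] + 1):
            if end - L < 0:
                continue
            seq = rep.sequence[end - L : end]
            if _passes(seq, c):
                out.append(Primer(seq, "fw", end - L + 1, end))
    out.sort(key=lambda p: _rank_key(p.sequence, p.ref_start))
    return out


def _reverse_candidates(
    anchor: Variant, rep: AlleleRecord, pa: PanelAlignment, c: PrimerConstraints
) -> list[Primer]:
    out = []
    for start in _anchor_end_candidates(anchor, rep.allele_id, pa):
        for L in range(c.length[0], c.length[1] + 1):
            if start - 1 + L > len(rep.sequence):
                continue
            window = rep.sequence[start - 1 : start - 1 + L]
            seq = revcomp(window)
            if _passes(seq, c):
                out.append(Primer(seq, "rv", start, start + L - 1))
    out.sort(key=lambda p: _rank_key(p.sequence, p.ref_start))
    return out


def _verify_pair(
    fw: Primer, rv: Primer, own_group: str, pa: PanelAlignment, c: PrimerConstraints
) -> int | None:
    """Own-group alleles must give exactly one product, other-group none.
    Returns the (majority) own-group product size, or None if verification fails."""
    own_sizes: list[int] = []
    for al in pa.panel:
        g = group_of(al)
        if g is None:
            continue
        sizes = _products(fw, rv, al.sequence, c)
        if g == own_group:
            if len(sizes) != 1:
                return None
            own_sizes.append(sizes[0])
        elif sizes:
            return None
    return _majority_size(own_sizes)


def design_allele_specific_pair(
    fw_anchor: Variant,
    rv_anchor: Variant,
    pa: PanelAlignment,
    constraints: PrimerConstraints | None = None,
    marker_name: str = "allele-specific",
    max_combinations: int = 12,
) -> PrimerSet:
    """Dominant marker: an Rf-specific and a Wf-specific primer pair anchored on
    diagnostic sites at the 3' termini, verified by in-silico PCR on the panel."""
    c = constraints or PrimerConstraints()
    groups = _group_alleles(pa.panel)
    if not groups["Rf"] or not groups["Wf"]:
        raise DesignError(f"{marker_name}: need alleles of both groups")
    pairs: dict[str, tuple[Primer, Primer]] = {}
    expected: dict[str, int] = {}
    for g in ("Rf", "Wf"):
        rep = groups[g][0]
        fw_cands = _forward_candidates(fw_anchor, rep, pa, c)
        rv_cands = _reverse_candidates(rv_anchor, rep, pa, c)
        if not fw_cands or not rv_cands:
            raise DesignError(
                f"{marker_name}: no constraint-passing {g} primer at the "
                f"{'forward' if not fw_cands else 'reverse'} anchor"
            )
        found = None
        tried = 0
        for fw in fw_cands:
            for rv in rv_cands:
                tried += 1
                if tried > max_combinations**2:
                    break
                size = _verify_pair(fw, rv, g, pa, c)
                if size is not None:
                    found = (fw, rv, size)
                    break
            if found or tried > max_combinations**2:
                break
        if not found:
            raise DesignError(
                f"{marker_name}: no {g}-specific pair discriminates the panel "
                f"(anchors ATG{fw_anchor.position:+d}/{rv_anchor.position:+d})"
            )
        pairs[g] = (found[0], found[1])
        expected[g] = found[2]
    return PrimerSet(
        marker_name=marker_name,
        mode="dominant_allele_specific_pair",
        pairs=pairs,
        expected_sizes=expected,
        anchors=(fw_anchor.position, rv_anchor.position),
        description=f"3'-anchored on {fw_anchor.kind} ATG{fw_anchor.position:+d} (fw) "
        f"and {rv_anchor.kind} ATG{rv_anchor.position:+d} (rv)",
    )


# ---------------------------------------------------------------------------
# the four-marker suite
# ---------------------------------------------------------------------------


def design_marker_suite(
    variants: Sequence[Variant],
    pa: PanelAlignment,
    model: GeneModel,
    constraints: PrimerConstraints | None = None,
    mask_variants: Sequence[Variant] | None = None,
    promoter_window: tuple[int, int] = (-979, -818),
) -> tuple[list[PrimerSet], list[DesignFailure]]:
    """Attempt the four marker types; failures are reported, never raised.

    ``variants`` supplies the classified diagnostic targets (discovery panel);
    ``mask_variants`` (default: the same) defines which reference positions
    count as polymorphic when primer windows must be conserved — pass the
    variant calls of a wider panel to keep primers clear of its private sites.
    """
    c = constraints or PrimerConstraints()
    mask_vars = list(mask_variants) if mask_variants is not None else list(variants)
    diag = [v for v in variants if v.specificity == "Rf_vs_Wf" and not v.ambiguous]
    sets: list[PrimerSet] = []
    failures: list[DesignFailure] = []

    def attempt(name: str, fn) -> None:
        try:
            sets.append(fn())
        except DesignError as exc:
            failures.append(DesignFailure(name, str(exc)))
            logger.warning("%s design failed: %s", name, exc)

    # PS-P: allele-specific pair on promoter SNPs inside the marker window
    def ps_p() -> PrimerSet:
        lo, hi = promoter_window
        window_snps = [
            v for v in diag
            if v.kind == "SNP" and v.region == "promoter" and lo <= v.position <= hi
        ]
        if len(window_snps) < 2:
            raise DesignError(
                f"PS-P: need >=2 diagnostic promoter SNPs in window {lo}..{hi}, "
                f"found {len(window_snps)}"
            )
        window_snps.sort(key=lambda v: v.genomic_pos)
        for fw_anchor in window_snps:
            for rv_anchor in reversed(window_snps):
                span = rv_anchor.genomic_pos - fw_anchor.genomic_pos + 1
                if span < c.product[0] or span > c.product[1]:
                    continue
                try:
                    return design_allele_specific_pair(
                        fw_anchor, rv_anchor, pa, c, marker_name="PS-P"
                    )
                except DesignError:
                    continue
        raise DesignError("PS-P: no anchored pair in the promoter window verified")

    # ID-P: codominant marker over the largest diagnostic promoter InDel
    def id_p() -> PrimerSet:
        indels = [v for v in diag if v.kind == "InDel" and v.region == "promoter"]
        if not indels:
            raise DesignError("ID-P: no diagnostic promoter InDel in the panel")
        target = max(indels, key=lambda v: v.length)
        return design_length_marker(target, pa, c, mask_vars, marker_name="ID-P")

    # SSR-P: codominant marker over the most size-divergent diagnostic SSR
    def ssr_p() -> PrimerSet:
        ssrs = [v for v in diag if v.kind == "SSR"]
        if not ssrs:
            raise DesignError("SSR-P: no diagnostic SSR in the panel")
        target = max(ssrs, key=expected_length_difference)
        return design_length_marker(target, pa, c, mask_vars, marker_name="SSR-P")

    # WD/AD-P: allele-specific pair from an intronic InDel into exonic SNPs
    def wdad_p() -> PrimerSet:
        intron_indels = sorted(
            (v for v in diag if v.kind == "InDel" and v.region.startswith("intron")),
            key=lambda v: -v.genomic_pos,  # prefer the most downstream (intron 5)
        )
        exon_snps = sorted(
            (v for v in diag if v.kind == "SNP" and v.region.startswith("exon")),
            key=lambda v: v.genomic_pos,
        )
        if not intron_indels or not exon_snps:
            raise DesignError(
                "WD/AD-P: needs a diagnostic intron InDel and a diagnostic exon SNP"
            )
        for indel in intron_indels:
            for snp in reversed(exon_snps):
                span = snp.genomic_pos - indel.genomic_pos + 1
                if span < c.product[0] or span > c.product[1]:
                    continue
                try:
                    return design_allele_specific_pair(
                        indel, snp, pa, c, marker_name="WD/AD-P"
                    )
                except DesignError:
                    continue
        raise DesignError("WD/AD-P: no intron-InDel/exon-SNP anchor combination verified")

    attempt("PS-P", ps_p)
    attempt("ID-P", id_p)
    attempt("SSR-P", ssr_p)
    attempt("WD/AD-P", wdad_p)
    return sets, failures


def markers_to_frame(sets: Sequence[PrimerSet], failures: Sequence[DesignFailure] = ()):
    import pandas as pd

    rows = []
    for m in sets:
        for key, (fw, rv) in sorted(m.pairs.items()):
            for primer in (fw, rv):
                rows.append(
                    {
                        "marker": m.marker_name,
                        "mode": m.mode,
                        "component": key,
                        "orientation": primer.orientation,
                        "sequence": primer.sequence,
                        "tm_wallace": compute_tm(primer.sequence),
                        "gc": round(gc_fraction(primer.sequence), 3),
                        "expected_sizes": ";".join(
                            f"{g}={s}" for g, s in sorted(m.expected_sizes.items())
                        ),
                        "anchors_atg": ";".join(f"{a:+d}" for a in m.anchors),
                        "status": "ok",
                    }
                )
    for f in failures:
        rows.append(
            {
                "marker": f.marker_name,
                "mode": "",
                "component": "",
                "orientation": "",
                "sequence": "",
                "tm_wallace": float("nan"),
                "gc": float("nan"),
                "expected_sizes": "",
                "anchors_atg": "",
                "status": f"failed: {f.reason}",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "marker", "mode", "component", "orientation", "sequence",
            "tm_wallace", "gc", "expected_sizes", "anchors_atg", "status",
        ],
    )
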