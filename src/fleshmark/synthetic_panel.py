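"""Synthetic allele-panel generator with a machine-readable truth set.

The generator emulates the data structure the marker pipeline assumes: one gene
(promoter + 7 exons + 6 introns), two haplotype groups (red-flesh Rf carried by
the GsRf/RsRf subtypes, white-flesh Wf carried by WsWf/RsWf), and a configurable
table of implanted polymorphisms.  Diagnostic variants separate all Rf from all
Wf alleles; subtype-specific variants are private to WsWf or RsWf; accessions are
diploid (homozygous or heterozygous) and the two alleles of an accession differ
additionally at a few nondiagnostic private SNPs, mimicking inbred-line panels
where the two cloned alleles of a line are distinct but equivalent for typing.

Mandatory features of the default configuration:

* a 14-nt insertion carried by the Wf haplotypes in the promoter, immediately
  upstream of the TSS, at ATG-relative position -35;
* a (TC) microsatellite in intron 2 with 13 repeats on Rf and 68 on Wf alleles;
* a 3-nt "CAT" deletion carried by Wf in intron 5;
* the exonic diagnostic SNPs in exon 6 (placed at synonymous third-codon
  positions so the encoded protein is conserved);
* diagnostic SNPs inside the promoter marker window -979..-818 (ATG-relative).

Every implanted variant is recorded in the truth set with its left-normalized
position, so the variant caller's output can be compared against it exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    AccessionMeta,
    AlleleRecord,
    GeneFeature,
    GeneModel,
    convert_coordinate,
    invert_coordinate,
)
from .variant_analysis import canonical_rotation, detect_ssr_loci, left_normalize

logger = logging.getLogger(__name__)

RF = ("GsRf", "RsRf")
WF = ("WsWf", "RsWf")
ALL_SUBTYPES = RF + WF


class ConfigError(ValueError):
    """Generator configuration cannot accommodate the requested features."""


class PlacementError(RuntimeError):
    """No collision-free placement found for an implanted variant."""


# ---------------------------------------------------------------------------
# specification of what to implant
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """Optional fixed attributes for one implanted variant.

    Any attribute left ``None`` is drawn at random.  ``position`` is
    ATG-relative (for InDels: the left-normalized position to aim for; for SSRs:
    the locus start).  ``feature`` pins the variant to a named gene feature such
    as ``'exon_6'``; ``feature_window`` restricts placement to a fraction of that
    feature's interior.
    """

    position: int | None = None
    feature: str | None = None
    feature_window: tuple[float, float] | None = None
    op: str | None = None  # InDel: 'ins' (alt carries insertion) | 'del'
    sequence: str | None = None
    length: int | None = None
    unit: str | None = None
    ref_repeats: int | None = None
    alt_repeats: int | None = None
    tag: str | None = None  # marks edits other modules need to find (e.g. 'tc_ssr')
    reserve: int = 0  # conserved flank (nt) kept free of later placements
    reserve_side: str = "both"  # both | left | right

    def reserved(self, lo: int, hi: int) -> tuple[int, int]:
        left = self.reserve if self.reserve_side in ("both", "left") else 0
        right = self.reserve if self.reserve_side in ("both", "right") else 0
        return (lo - left, hi + right)


@dataclass(frozen=True)
class PolymorphismSpec:
    kind: str  # SNP | InDel | SSR
    region: str  # promoter | exon | intron (region class)
    specificity: str  # Rf_vs_Wf | WsWf_specific | RsWf_specific
    count: int
    placements: tuple[Placement, ...] = ()

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigError("spec counts must be nonnegative")
        if len(self.placements) > self.count:
            raise ConfigError("more fixed placements than the spec count")


def default_spec_table(mandatory_features: bool = True) -> tuple[PolymorphismSpec, ...]:
    """Default implant table: the published polymorphism counts per region class,
    kind and specificity class, with the mandatory marker-bearing features fixed."""
    P = Placement
    m = mandatory_features
    return (
        PolymorphismSpec(
            "SNP", "promoter", "Rf_vs_Wf", 16,
            placements=(
                P(position=-975, reserve=28, reserve_side="left"),
                P(position=-930),
                P(position=-870),
                P(position=-822, reserve=28, reserve_side="right"),
            ) if m else (),
        ),
        PolymorphismSpec(
            "InDel", "promoter", "Rf_vs_Wf", 2,
            placements=(P(position=-35, op="ins", length=14, tag="idp_indel", reserve=60),)
            if m else (),
        ),
        PolymorphismSpec("SSR", "promoter", "Rf_vs_Wf", 1),
        PolymorphismSpec(
            "SNP", "exon", "Rf_vs_Wf", 2,
            placements=(
                P(feature="exon_6", feature_window=(0.1, 0.5), reserve=30),
                P(feature="exon_6", feature_window=(0.5, 0.9), reserve=30),
            ) if m else (),
        ),
        PolymorphismSpec("SNP", "intron", "Rf_vs_Wf", 10),
        PolymorphismSpec(
            "InDel", "intron", "Rf_vs_Wf", 1,
            placements=(
                P(feature="intron_5", feature_window=(0.1, 0.4), op="del",
                  sequence="CAT", tag="wdad_indel", reserve=60),
            ) if m else (),
        ),
        PolymorphismSpec(
            "SSR", "intron", "Rf_vs_Wf", 2,
            placements=(
                P(feature="intron_2", unit="TC", ref_repeats=13, alt_repeats=68,
                  tag="tc_ssr", reserve=80),
            ) if m else (),
        ),
        PolymorphismSpec("SNP", "promoter", "WsWf_specific", 2),
        PolymorphismSpec("InDel", "promoter", "WsWf_specific", 4),
        PolymorphismSpec("SSR", "promoter", "WsWf_specific", 1),
        PolymorphismSpec("SNP", "exon", "WsWf_specific", 1),
        PolymorphismSpec("SNP", "intron", "WsWf_specific", 3),
        PolymorphismSpec("InDel", "intron", "WsWf_specific", 3),
        PolymorphismSpec("SSR", "intron", "WsWf_specific", 2),
        PolymorphismSpec("SNP", "promoter", "RsWf_specific", 2),
        PolymorphismSpec("SNP", "exon", "RsWf_specific", 3),
        PolymorphismSpec("InDel", "exon", "RsWf_specific", 1),
        PolymorphismSpec("SNP", "intron", "RsWf_specific", 4),
        PolymorphismSpec("SSR", "intron", "RsWf_specific", 1),
    )


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic panel.

    Default feature lengths give a ~3.5 kb gene with a 1 kb promoter and a 20-nt
    5'UTR (so ATG-relative -35 falls 15 nt upstream of the TSS, inside the
    promoter).  The coding span from the ATG is a multiple of 3.
    """

    seed: int = 0
    promoter_length: int = 1000
    utr5_length: int = 20
    exon_lengths: tuple[int, ...] = (220, 150, 120, 96, 90, 210, 400)
    intron_lengths: tuple[int, ...] = (150, 400, 150, 120, 220, 160)
    gc_fraction: float = 0.40
    spec_table: tuple[PolymorphismSpec, ...] | None = None
    mandatory_features: bool = True
    pair_snps: int = 3  # private nondiagnostic SNPs between an accession's alleles
    exonic_snps_synonymous: bool = True
    min_spacing: int = 10
    max_attempts: int = 30

    def table(self) -> tuple[PolymorphismSpec, ...]:
        if self.spec_table is not None:
            return self.spec_table
        return default_spec_table(self.mandatory_features)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------


def build_gene_model(config: GeneratorConfig, reference_id: str = "reference") -> GeneModel:
    if min(config.exon_lengths) <= 0 or min(config.intron_lengths) <= 0:
        raise ConfigError("feature lengths must be positive")
    if len(config.exon_lengths) != len(config.intron_lengths) + 1:
        raise ConfigError("need one more exon than introns")
    feats: list[GeneFeature] = [GeneFeature("promoter", 1, 1, config.promoter_length)]
    pos = config.promoter_length + 1
    for i, elen in enumerate(config.exon_lengths, start=1):
        feats.append(GeneFeature("exon", i, pos, pos + elen - 1))
        pos += elen
        if i <= len(config.intron_lengths):
            ilen = config.intron_lengths[i - 1]
            feats.append(GeneFeature("intron", i, pos, pos + ilen - 1))
            pos += ilen
    tss = config.promoter_length + 1
    atg = tss + config.utr5_length
    if config.exon_lengths[0] <= config.utr5_length + 3:
        raise ConfigError("exon 1 too short for the 5'UTR and start codon")
    model = GeneModel(
        reference_allele_id=reference_id,
        features=tuple(feats),
        tss_pos=tss,
        atg_pos=atg,
    )
    strict = len(config.exon_lengths) == 7
    return model.validate(strict_structure=strict)


def generate_reference(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[str, GeneModel]:
    """Random reference sequence with the configured GC fraction, plus its model."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    model = build_gene_model(config)
    if not 0.0 < config.gc_fraction < 1.0:
        raise ConfigError("gc_fraction must be in (0, 1)")
    p_gc = config.gc_fraction / 2
    p_at = (1 - config.gc_fraction) / 2
    seq = rng.choice(list("ACGT"), size=model.length, p=[p_at, p_gc, p_gc, p_at])
    if config.mandatory_features:
        _check_mandatory_fit(config, model)
    return "".join(seq), model


def _check_mandatory_fit(config: GeneratorConfig, model: GeneModel) -> None:
    for spec in config.table():
        for pl in spec.placements:
            if pl.unit and pl.feature:
                feat = model.feature(pl.feature)
                need = len(pl.unit) * max(pl.ref_repeats or 4, 4) + 2 * (pl.reserve + 4)
                if feat.length < need:
                    raise ConfigError(
                        f"{pl.feature} too short ({feat.length} nt) for the "
                        f"{pl.unit} microsatellite plus conserved flanks ({need} nt)"
                    )
            if pl.position is not None:
                try:
                    invert_coordinate(pl.position, "atg", model)
                except Exception as exc:  # noqa: BLE001
                    raise ConfigError(
                        f"fixed placement at ATG-relative {pl.position} does not fit "
                        f"the gene model"
                    ) from exc


# ---------------------------------------------------------------------------
# edits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Edit:
    kind: str  # SNP | ins | del | SSR
    pos: int  # genomic 1-based; ins: reference base before which the insertion sits
    ref: str
    alt: str
    tag: str | None = None

    @property
    def footprint(self) -> tuple[int, int]:
        if self.kind == "SNP":
            return (self.pos, self.pos)
        if self.kind == "ins":
            return (self.pos - 1, self.pos)
        return (self.pos, self.pos + len(self.ref) - 1)


def apply_edits(reference: str, edits: Sequence[_Edit]) -> str:
    seq = reference
    for e in sorted(edits, key=lambda e: e.pos, reverse=True):
        i = e.pos - 1
        if e.kind == "SNP":
            seq = seq[:i] + e.alt + seq[i + 1 :]
        elif e.kind == "ins":
            seq = seq[:i] + e.alt + seq[i:]
        elif e.kind in ("del", "SSR"):
            seq = seq[:i] + e.alt + seq[i + len(e.ref) :]
        else:  # pragma: no cover
            raise ValueError(f"unknown edit kind {e.kind}")
    return seq


# ---------------------------------------------------------------------------
# placement machinery
# ---------------------------------------------------------------------------


class _Registry:
    """Occupied genomic intervals; placements must keep ``spacing`` nt clear."""

    def __init__(self, spacing: int) -> None:
        self.spacing = spacing
        self.intervals: list[tuple[int, int]] = []

    def free(self, start: int, end: int, spacing: int | None = None) -> bool:
        pad = self.spacing if spacing is None else spacing
        s, e = start - pad, end + pad
        return all(e < a or s > b for a, b in self.intervals)

    def add(self, start: int, end: int) -> None:
        self.intervals.append((start, end))


def _region_spans(model: GeneModel, region: str, margin: int = 12) -> list[tuple[int, int]]:
    spans = []
    for f in model.features:
        if (region == "promoter" and f.kind == "promoter") or f.name == region or (
            region in ("exon", "intron") and f.kind == region
        ):
            lo, hi = f.start + margin, f.end - margin
            if lo <= hi:
                spans.append((lo, hi))
    if not spans:
        raise ConfigError(f"no placeable span for region {region!r}")
    return spans


def _sample_start(
    rng: np.random.Generator,
    spans: Sequence[tuple[int, int]],
    width: int,
    registry: _Registry,
    tries: int = 400,
    spacing: int | None = None,
) -> int:
    usable = [(lo, hi - width + 1) for lo, hi in spans if hi - width + 1 >= lo]
    if not usable:
        raise PlacementError(f"no span can hold a footprint of {width} nt")
    weights = np.array([hi - lo + 1 for lo, hi in usable], dtype=float)
    weights /= weights.sum()
    for _ in range(tries):
        lo, hi = usable[rng.choice(len(usable), p=weights)]
        start = int(rng.integers(lo, hi + 1))
        if registry.free(start, start + width - 1, spacing=spacing):
            return start
    raise PlacementError(f"could not place a {width}-nt footprint after {tries} tries")


_FOURFOLD_PREFIXES = ("GC", "GG", "CC", "AC", "GT", "CT", "TC", "CG")


def _codon_starts(model: GeneModel, feature: str | None) -> list[int]:
    """Genomic starts of codons lying entirely inside one exon (interior)."""
    cds = model.cds_positions()
    out = []
    for i in range(0, len(cds) - 2, 3):
        a, b, c = cds[i], cds[i + 1], cds[i + 2]
        if c != a + 2:
            continue
        feat = model.feature_at(a)
        if feature is not None and feat.name != feature:
            continue
        if a < feat.start + 10 or c > feat.end - 10:
            continue
        out.append(a)
    return out


def _random_base(rng: np.random.Generator, exclude: str = "") -> str:
    options = [b for b in "ACGT" if b not in exclude]
    return options[int(rng.integers(len(options)))]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_random_base(rng) for _ in range(length))


# ---------------------------------------------------------------------------
# implanting
# ---------------------------------------------------------------------------


@dataclass
class ImplantResult:
    """Reference (with installed repeat blocks / codon contexts), per-subtype
    haplotypes and edits, the implanted truth table, and the placement registry
    that panel building continues to use for private SNPs."""

    reference: str
    model: GeneModel
    edits: dict[str, list[_Edit]]
    truth: pd.DataFrame
    registry: _Registry
    tagged: dict[str, _Edit]

    @property
    def haplotypes(self) -> dict[str, str]:
        return {st: apply_edits(self.reference, self.edits[st]) for st in ALL_SUBTYPES}


_TRUTH_COLUMNS = [
    "kind", "position", "genomic_pos", "region", "specificity",
    "length", "unit", "ref_state", "alt_state", "carriers",
]


def _carriers(specificity: str) -> tuple[str, ...]:
    return {
        "Rf_vs_Wf": WF,
        "WsWf_specific": ("WsWf",),
        "RsWf_specific": ("RsWf",),
    }[specificity]


def implant_variants(
    reference: str,
    model: GeneModel,
    spec_table: Sequence[PolymorphismSpec],
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> ImplantResult:
    """Install the spec table into the reference and derive group haplotypes.

    The reference itself may be rewritten locally (microsatellite blocks with
    repeat-breaking flanks; synonymous-codon contexts for exonic SNPs) so that
    every implanted variant is recoverable at exactly its recorded coordinates.
    """
    config = config or GeneratorConfig()
    ref = list(reference)
    registry = _Registry(config.min_spacing)
    # block placements on/near repeat runs already present in the random sequence,
    # so indel left-normalization cannot slide an event into them
    for loc in detect_ssr_loci("".join(ref)):
        registry.add(loc.start - 2, loc.end + 2)

    edits: dict[str, list[_Edit]] = {st: [] for st in ALL_SUBTYPES}
    tagged: dict[str, _Edit] = {}
    truth_rows: list[dict] = []

    def record(edit: _Edit, spec: PolymorphismSpec, *, kind: str, position: int,
               length: int, unit: str | None, ref_state, alt_state) -> None:
        for st in _carriers(spec.specificity):
            edits[st].append(edit)
        if edit.tag:
            tagged[edit.tag] = edit
        truth_rows.append(
            {
                "kind": kind,
                "position": convert_coordinate(position, "atg", model),
                "genomic_pos": position,
                "region": model.region_name(position),
                "specificity": spec.specificity,
                "length": length,
                "unit": unit or "",
                "ref_state": ref_state,
                "alt_state": alt_state,
                "carriers": ",".join(_carriers(spec.specificity)),
            }
        )

    def place_snp(spec: PolymorphismSpec, pl: Placement) -> None:
        pos = _resolve_pos(pl, spec)
        target = pl.feature or spec.region
        exonic = target == "exon" or target.startswith("exon_")
        if pos is None and exonic and config.exonic_snps_synonymous:
            _place_synonymous_snp(spec, pl)
            return
        if pos is None:
            spans = _region_spans(model, target)
            pos = _sample_start(rng, spans, 1, registry)
        elif not registry.free(pos, pos):
            raise PlacementError(f"fixed SNP position {pos} collides")
        ref_base = ref[pos - 1]
        alt = _random_base(rng, exclude=ref_base)
        edit = _Edit("SNP", pos, ref_base, alt, tag=pl.tag)
        registry.add(*pl.reserved(pos, pos))
        record(edit, spec, kind="SNP", position=pos, length=1, unit=None,
               ref_state=ref_base, alt_state=alt)

    def _place_synonymous_snp(spec: PolymorphismSpec, pl: Placement) -> None:
        feature = pl.feature if pl.feature else spec.region
        feature = None if feature in ("exon", "intron", "promoter") else feature
        candidates = _codon_starts(model, feature)
        if pl.feature_window and feature:
            f = model.feature(feature)
            lo = f.start + pl.feature_window[0] * f.length
            hi = f.start + pl.feature_window[1] * f.length
            windowed = [c for c in candidates if lo <= c <= hi]
            candidates = windowed or candidates
        rng.shuffle(candidates)
        for c in candidates:
            if not registry.free(c, c + 2):
                continue
            prefix = _FOURFOLD_PREFIXES[int(rng.integers(len(_FOURFOLD_PREFIXES)))]
            ref_third = _random_base(rng)
            alt_third = _random_base(rng, exclude=ref_third)
            ref[c - 1 : c + 2] = list(prefix + ref_third)
            pos = c + 2
            edit = _Edit("SNP", pos, ref_third, alt_third, tag=pl.tag)
            registry.add(*pl.reserved(c, c + 2))
            record(edit, spec, kind="SNP", position=pos, length=1, unit=None,
                   ref_state=ref_third, alt_state=alt_third)
            return
        raise PlacementError(f"no free synonymous codon site for {spec.region} SNP")

    def place_indel(spec: PolymorphismSpec, pl: Placement) -> None:
        op = pl.op or ("ins" if rng.integers(2) else "del")
        if pl.sequence is not None:
            length = len(pl.sequence)
        elif pl.length is not None:
            length = pl.length
        elif spec.region == "exon":
            length = 3 * int(rng.integers(1, 3))  # in-frame by default
        else:
            length = int(rng.integers(2, 11))
        pos = _resolve_pos(pl, spec)
        width = length if op == "del" else 2
        if pos is None:
            spans = _region_spans(model, pl.feature or spec.region, margin=14)
            if pl.feature_window and pl.feature:
                f = model.feature(pl.feature)
                lo = int(f.start + pl.feature_window[0] * f.length)
                hi = int(f.start + pl.feature_window[1] * f.length)
                spans = [(lo, hi)]
            pos = _sample_start(rng, spans, width + 2, registry) + 1
        elif not registry.free(pos - 1, pos + width):
            raise PlacementError(f"fixed InDel position {pos} collides")

        if op == "del":
            if pl.sequence is not None:
                ref[pos - 1 : pos + length - 1] = list(pl.sequence)
            seq = "".join(ref[pos - 1 : pos + length - 1])
            # forbid left-shift: base before the run must differ from its last base
            if pos > 1 and ref[pos - 2] == seq[-1]:
                ref[pos - 2] = _random_base(rng, exclude=seq[-1] + ref[pos - 3])
            # forbid right-shift: base after the run must differ from its first base
            if ref[pos + length - 1] == seq[0]:
                ref[pos + length - 1] = _random_base(rng, exclude=seq[0] + (ref[pos + length] if pos + length < len(ref) else ""))
            edit = _Edit("del", pos, seq, "", tag=pl.tag)
            foot = (pos, pos + length - 1)
            ref_state, alt_state = seq, "-"
        else:
            seq = pl.sequence or _random_seq(rng, length)
            # make the placement its own left-normal form and shift-free
            tries = 0
            while pos > 1 and (seq[-1] == ref[pos - 2] or seq[0] == ref[pos - 1]):
                if pl.sequence is not None:
                    # fixed content: adjust the flanks instead
                    if seq[-1] == ref[pos - 2]:
                        ref[pos - 2] = _random_base(rng, exclude=seq[-1])
                    if seq[0] == ref[pos - 1]:
                        ref[pos - 1] = _random_base(rng, exclude=seq[0])
                    break
                seq = _random_seq(rng, length)
                tries += 1
                if tries > 50:
                    raise PlacementError("cannot draw a shift-free insertion")
            edit = _Edit("ins", pos, "", seq, tag=pl.tag)
            foot = (pos - 1, pos)
            ref_state, alt_state = "-", seq
        npos, nseq = left_normalize("".join(ref), pos, op, seq)
        if (npos, nseq) != (pos, seq):
            raise PlacementError("indel placement is not left-normal")
        registry.add(*pl.reserved(*foot))
        record(edit, spec, kind="InDel", position=pos, length=length, unit=None,
               ref_state=ref_state, alt_state=alt_state)

    _SSR_UNITS = ("TC", "AG", "AC", "TG", "TTC", "ATG")

    def place_ssr(spec: PolymorphismSpec, pl: Placement) -> None:
        unit = pl.unit or _SSR_UNITS[int(rng.integers(len(_SSR_UNITS)))]
        u = len(unit)
        ref_rep = pl.ref_repeats or int(rng.integers(5, 11))
        alt_rep = pl.alt_repeats
        if alt_rep is None:
            delta = int(rng.integers(3, 9)) * (1 if rng.integers(2) else -1)
            alt_rep = max(2, ref_rep + delta)
            if alt_rep == ref_rep:
                alt_rep = ref_rep + 3
        block_len = u * ref_rep
        pos = _resolve_pos(pl, spec)
        if pos is None:
            spans = _region_spans(model, pl.feature or spec.region, margin=14)
            if pl.feature_window and pl.feature:
                f = model.feature(pl.feature)
                spans = [
                    (
                        int(f.start + pl.feature_window[0] * f.length),
                        int(f.start + pl.feature_window[1] * f.length),
                    )
                ]
            pos = _sample_start(rng, spans, block_len + 4, registry) + 1
        elif not registry.free(pos - 2, pos + block_len + 1):
            raise PlacementError(f"fixed SSR position {pos} collides")
        # install the repeat block with repeat-breaking flanking bases
        ref[pos - 1 : pos + block_len - 1] = list(unit * ref_rep)
        ref[pos - 2] = _random_base(rng, exclude=unit[-1] + ref[pos - 3])
        after = pos + block_len - 1
        ref[after] = _random_base(rng, exclude=unit[0] + (ref[after + 1] if after + 1 < len(ref) else ""))
        edit = _Edit("SSR", pos, unit * ref_rep, unit * alt_rep, tag=pl.tag)
        registry.add(*pl.reserved(pos - 1, pos + block_len))
        record(edit, spec, kind="SSR", position=pos,
               length=abs(alt_rep - ref_rep) * u, unit=canonical_rotation(unit),
               ref_state=ref_rep, alt_state=alt_rep)

    def _resolve_pos(pl: Placement, spec: PolymorphismSpec) -> int | None:
        if pl.position is None:
            return None
        return invert_coordinate(pl.position, "atg", model)

    placers = {"SNP": place_snp, "InDel": place_indel, "SSR": place_ssr}
    # fixed placements first so reserved marker regions are protected, then the
    # random ones largest-footprint first so repeat blocks and indels find room
    todo: list[tuple[PolymorphismSpec, Placement]] = []
    for spec in spec_table:
        for pl in spec.placements:
            todo.append((spec, pl))
    kind_order = {"SSR": 0, "InDel": 1, "SNP": 2}
    randoms: list[tuple[PolymorphismSpec, Placement]] = []
    for spec in spec_table:
        for _ in range(spec.count - len(spec.placements)):
            randoms.append((spec, Placement()))
    randoms.sort(key=lambda sp: kind_order[sp[0].kind])
    for spec, pl in todo + randoms:
        placers[spec.kind](spec, pl)

    final_ref = "".join(ref)
    truth = pd.DataFrame(truth_rows, columns=_TRUTH_COLUMNS)
    result = ImplantResult(
        reference=final_ref,
        model=model,
        edits=edits,
        truth=truth,
        registry=registry,
        tagged=tagged,
    )
    _validate_implant(result)
    return result


def _validate_implant(result: ImplantResult) -> None:
    """Re-derive every implanted variant's coordinates on the final reference and
    fail (forcing a retry with a fresh layout) on any ambiguity."""
    ref = result.reference
    loci = detect_ssr_loci(ref)
    loci_by_start = {l.start: l for l in loci}
    for row in result.truth.itertuples(index=False):
        if row.kind == "SSR":
            loc = loci_by_start.get(row.genomic_pos)
            if loc is None or loc.unit != row.unit or loc.repeats != row.ref_state:
                raise PlacementError(
                    f"installed SSR at {row.genomic_pos} not detected as intended"
                )
        else:
            lo = row.genomic_pos - 2
            hi = row.genomic_pos + int(row.length) + 1
            for loc in loci:
                if not (hi < loc.start or lo > loc.end):
                    raise PlacementError(
                        f"{row.kind} at {row.genomic_pos} abuts repeat locus "
                        f"{loc.unit}@{loc.start}"
                    )
        if row.kind == "InDel":
            op = "del" if row.alt_state == "-" else "ins"
            seq = row.ref_state if op == "del" else row.alt_state
            npos, _ = left_normalize(ref, row.genomic_pos, op, str(seq))
            if npos != row.genomic_pos:
                raise PlacementError(f"InDel at {row.genomic_pos} is not left-normal")


# ---------------------------------------------------------------------------
# top-level build with retry
# ---------------------------------------------------------------------------


def build_haplotypes(config: GeneratorConfig) -> ImplantResult:
    """Generate reference + implant the spec table, retrying with a fresh random
    layout (still derived deterministically from the seed) if a layout cannot be
    validated."""
    last: Exception | None = None
    for attempt in range(config.max_attempts):
        rng = np.random.default_rng([config.seed % (2**31), attempt])
        try:
            reference, model = generate_reference(config, rng)
            return implant_variants(reference, model, config.table(), rng, config)
        except PlacementError as exc:
            last = exc
            logger.debug("layout attempt %d rejected: %s", attempt, exc)
    raise PlacementError(f"no valid layout after {config.max_attempts} attempts: {last}")


# ---------------------------------------------------------------------------
# panels of diploid accessions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccessionPlan:
    accession_id: str
    line_name: str
    subtypes: tuple[str, str]
    phenotype: str
    rf_type_ssr: bool = False  # homoplasy: carry the Rf-length microsatellite


def default_discovery_plan() -> tuple[AccessionPlan, ...]:
    """Four homozygous inbred lines, one per skin/flesh subtype — the panel on
    which polymorphisms are discovered and markers designed."""
    return (
        AccessionPlan("GsRf_TT8", "HKR-397", ("GsRf", "GsRf"), "red"),
        AccessionPlan("RsRf_TT8", "HKR-275", ("RsRf", "RsRf"), "red"),
        AccessionPlan("WsWf_TT8", "HKR-519", ("WsWf", "WsWf"), "white"),
        AccessionPlan("RsWf_TT8", "HKR-513", ("RsWf", "RsWf"), "white"),
    )


def default_validation_plan(chengwoo: bool = False) -> tuple[AccessionPlan, ...]:
    """A wider panel: inbred and breeding lines plus heterozygous F1 cultivars.

    With ``chengwoo=True``, adds a white-fleshed accession that carries the
    Rf-length microsatellite (the homoplasy that breaks the SSR marker)."""
    plan = [
        AccessionPlan("VAL-GsRf", "V-397", ("GsRf", "GsRf"), "red"),
        AccessionPlan("VAL-RsRf", "V-275", ("RsRf", "RsRf"), "red"),
        AccessionPlan("VAL-WsWf", "V-519", ("WsWf", "WsWf"), "white"),
        AccessionPlan("VAL-RsWf", "V-513", ("RsWf", "RsWf"), "white"),
        AccessionPlan("BR-101", "BR-101", ("RsRf", "RsRf"), "red"),
        AccessionPlan("BR-102", "BR-102", ("WsWf", "WsWf"), "white"),
        AccessionPlan("RedSun", "RedSun", ("RsRf", "WsWf"), "red"),
        AccessionPlan("Rupr", "Rupr", ("RsRf", "RsWf"), "red"),
        AccessionPlan("Anthopol", "Anthopol", ("GsRf", "WsWf"), "red"),
    ]
    if chengwoo:
        plan.append(
            AccessionPlan("Chengwoo", "Chengwoo", ("WsWf", "WsWf"), "white", rf_type_ssr=True)
        )
    return tuple(plan)


@dataclass
class Panel:
    alleles: list[AlleleRecord]
    accessions: list[AccessionMeta]
    truth: pd.DataFrame  # implanted rows + this panel's private nondiagnostic SNPs


def build_panel(
    build: ImplantResult,
    plan: Sequence[AccessionPlan],
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> Panel:
    """Emit diploid accessions from the haplotypes.

    Allele 1 of each accession is the pure subtype haplotype; allele 2 carries
    ``pair_snps`` additional private SNPs at nondiagnostic positions (placed in
    noncoding regions, clear of all implanted variants and repeat loci).
    """
    if not plan:
        raise ValueError("empty accession plan")
    config = config or GeneratorConfig()
    model = build.model
    alleles: list[AlleleRecord] = []
    accessions: list[AccessionMeta] = []
    private_rows: list[dict] = []
    noncoding = _region_spans(model, "promoter") + _region_spans(model, "intron")

    for acc in plan:
        allele_ids = []
        for i, subtype in enumerate(acc.subtypes, start=1):
            aid = f"{acc.accession_id}_{i}"
            allele_ids.append(aid)
            subtype_edits = list(build.edits[subtype])
            if acc.rf_type_ssr:
                subtype_edits = [e for e in subtype_edits if e.tag != "tc_ssr"]
            private: list[_Edit] = []
            if i == 2:
                for _ in range(config.pair_snps):
                    # isolated substitutions need little clearance; reserved
                    # marker windows stay blocked regardless of spacing
                    pos = _sample_start(rng, noncoding, 1, build.registry, spacing=4)
                    ref_base = build.reference[pos - 1]
                    alt = _random_base(rng, exclude=ref_base)
                    build.registry.add(pos, pos)
                    private.append(_Edit("SNP", pos, ref_base, alt))
                    private_rows.append(
                        {
                            "kind": "SNP",
                            "position": convert_coordinate(pos, "atg", model),
                            "genomic_pos": pos,
                            "region": model.region_name(pos),
                            "specificity": "nondiagnostic",
                            "length": 1,
                            "unit": "",
                            "ref_state": ref_base,
                            "alt_state": alt,
                            "carriers": aid,
                        }
                    )
            seq = apply_edits(build.reference, subtype_edits + private)
            alleles.append(
                AlleleRecord(
                    allele_id=aid,
                    accession_id=acc.accession_id,
                    group=None,
                    subtype=subtype,
                    sequence=seq,
                )
            )
        accessions.append(
            AccessionMeta(
                accession_id=acc.accession_id,
                line_name=acc.line_name,
                observed_flesh=acc.phenotype,
                allele_ids=tuple(allele_ids),
                subtype=acc.subtypes[0] if acc.subtypes[0] == acc.subtypes[1] else None,
            )
        )
    truth = pd.concat(
        [build.truth, pd.DataFrame(private_rows, columns=_TRUTH_COLUMNS)],
        ignore_index=True,
    )
    truth = truth.sort_values("genomic_pos", kind="stable").reset_index(drop=True)
    return Panel(alleles=alleles, accessions=accessions, truth=truth)


@dataclass
class Experiment:
    """Discovery and validation panels generated from one haplotype build."""

    config: GeneratorConfig
    build: ImplantResult
    discovery: Panel
    validation: Panel

    @property
    def model(self) -> GeneModel:
        return self.build.model

    @property
    def reference_id(self) -> str:
        rf = sorted(
            a.allele_id
            for a in self.discovery.alleles
            if a.subtype in RF
        )
        return rf[0]


def simulate_experiment(
    config: GeneratorConfig | None = None,
    discovery_plan: Sequence[AccessionPlan] | None = None,
    validation_plan: Sequence[AccessionPlan] | None = None,
    chengwoo: bool = False,
) -> Experiment:
    """One seeded end-to-end dataset: haplotypes, a discovery panel and a
    validation panel sharing the same placement registry (so their private SNPs
    never collide when the panels are analysed jointly)."""
    config = config or GeneratorConfig()
    build = build_haplotypes(config)
    rng = np.random.default_rng([config.seed % (2**31), 9999])
    discovery = build_panel(
        build, discovery_plan or default_discovery_plan(), rng, config
    )
    validation = build_panel(
        build, validation_plan or default_validation_plan(chengwoo=chengwoo), rng, config
    )
    model = replace(build.model, reference_allele_id=sorted(
        a.allele_id for a in discovery.alleles if a.subtype in RF
    )[0])
    build.model = model
    return Experiment(config=config, build=build, discovery=discovery, validation=validation)
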