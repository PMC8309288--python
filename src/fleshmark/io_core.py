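"""Standard-format I/O, the anchor-relative coordinate system, and gene-model validation.

Everything downstream works on a single gene cloned from a panel of accessions:
allele sequences arrive as FASTA in gene orientation (plus strand), the gene model
(promoter + exons + introns with TSS/ATG anchors) as a small GFF3 subset, and
accession metadata (line name, flesh phenotype, allele ids) as TSV.

Coordinates are 1-based inclusive.  Anchor-relative positions skip zero: the anchor
base itself is +1 and the base immediately 5' of it is -1, matching the breeder's
"-35" / "-979~-818" convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RF_SUBTYPES = frozenset({"GsRf", "RsRf"})
WF_SUBTYPES = frozenset({"WsWf", "RsWf"})
SUBTYPES = RF_SUBTYPES | WF_SUBTYPES
PHENOTYPES = frozenset({"red", "white", "pink", "segregating", "unknown"})

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed input file (duplicate ids, bad columns, bad bases)."""


class LinkageError(ValueError):
    """Metadata and sequence files do not reference each other consistently."""


class ModelError(ValueError):
    """Gene model violates its structural invariants."""


class CoordinateError(ValueError):
    """Position outside the reference span or invalid anchor-relative value."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneFeature:
    kind: str  # promoter | exon | intron
    index: int  # 1-based within kind; promoter has index 1
    start: int  # 1-based inclusive
    end: int

    @property
    def name(self) -> str:
        return "promoter" if self.kind == "promoter" else f"{self.kind}_{self.index}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """Promoter/exon/intron layout of one gene on its reference allele.

    Invariants (checked by :meth:`validate`): the promoter ends immediately before
    the TSS; exons and introns alternate and tile the post-promoter span without
    gaps or overlap; ``atg_pos >= tss_pos``.  When ``strict_structure`` the model
    must have exactly 7 exons and 6 introns (the RsTT8 layout).
    """

    reference_allele_id: str
    features: tuple[GeneFeature, ...]
    tss_pos: int
    atg_pos: int
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", tuple(self.features))

    # -- structure ----------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        return (min(f.start for f in self.features), max(f.end for f in self.features))

    @property
    def length(self) -> int:
        lo, hi = self.span
        return hi - lo + 1

    def exons(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "exon"]

    def introns(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "intron"]

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise ModelError(f"no feature named {name!r}")

    def feature_at(self, pos: int) -> GeneFeature:
        for f in self.features:
            if f.start <= pos <= f.end:
                return f
        lo, hi = self.span
        raise CoordinateError(f"position {pos} outside model span {lo}..{hi}")

    def region_name(self, pos: int) -> str:
        return self.feature_at(pos).name

    def validate(self, strict_structure: bool = True) -> "GeneModel":
        if self.strand != "+":
            raise ModelError("alleles must be stored in gene orientation (plus strand)")
        feats = sorted(self.features, key=lambda f: f.start)
        if not feats or feats[0].kind != "promoter":
            raise ModelError("model must start with a promoter feature")
        for f in feats:
            if f.start > f.end:
                raise ModelError(f"feature {f.name} has start > end")
        for a, b in zip(feats, feats[1:]):
            if a.end + 1 != b.start:
                raise ModelError(
                    f"features {a.name} and {b.name} do not abut: "
                    f"{a.name} ends at {a.end}, {b.name} starts at {b.start}"
                )
        body = feats[1:]
        if not body or body[0].kind != "exon" or body[-1].kind != "exon":
            raise ModelError("post-promoter span must start and end with an exon")
        for i, f in enumerate(body):
            expect = "exon" if i % 2 == 0 else "intron"
            if f.kind != expect:
                raise ModelError(f"feature order broken at {f.name}: expected {expect}")
            if f.index != i // 2 + 1:
                raise ModelError(f"feature {f.kind} index {f.index} out of order")
        n_exon, n_intron = len(self.exons()), len(self.introns())
        if strict_structure and (n_exon, n_intron) != (7, 6):
            raise ModelError(
                f"expected 7 exons and 6 introns, got {n_exon} exons / {n_intron} introns"
            )
        promoter = feats[0]
        if promoter.end + 1 != self.tss_pos:
            raise ModelError("promoter must end immediately before the TSS")
        if self.atg_pos < self.tss_pos:
            raise ModelError("ATG cannot precede the TSS")
        lo, hi = self.span
        if not (lo <= self.atg_pos <= hi):
            raise ModelError("ATG outside the model span")
        return self

    # -- coding geometry ----------------------------------------------------

    def cds_positions(self) -> list[int]:
        """Genomic positions of coding bases: exonic bases from the ATG onward."""
        out: list[int] = []
        for f in self.exons():
            for p in range(max(f.start, self.atg_pos), f.end + 1):
                out.append(p)
        return out


@dataclass(frozen=True)
class AlleleRecord:
    allele_id: str
    accession_id: str
    group: str | None  # Rf | Wf
    subtype: str | None  # GsRf | RsRf | WsWf | RsWf
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"allele {self.allele_id}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(f"allele {self.allele_id}: invalid bases {sorted(bad)}")
        if self.subtype is not None:
            if self.subtype not in SUBTYPES:
                raise FormatError(f"allele {self.allele_id}: unknown subtype {self.subtype}")
            expected = "Rf" if self.subtype in RF_SUBTYPES else "Wf"
            if self.group is not None and self.group != expected:
                raise FormatError(
                    f"allele {self.allele_id}: group {self.group} inconsistent "
                    f"with subtype {self.subtype}"
                )
            if self.group is None:
                object.__setattr__(self, "group", expected)


@dataclass(frozen=True)
class AccessionMeta:
    accession_id: str
    line_name: str
    observed_flesh: str  # red | white | pink | segregating | unknown
    allele_ids: tuple[str, ...]
    subtype: str | None = None

    def __post_init__(self) -> None:
        if self.observed_flesh not in PHENOTYPES:
            raise FormatError(
                f"accession {self.accession_id}: phenotype {self.observed_flesh!r} "
                f"not one of {sorted(PHENOTYPES)}"
            )
        ids = tuple(self.allele_ids)
        if not 1 <= len(ids) <= 2:
            raise FormatError(f"accession {self.accession_id}: diploid, needs 1-2 alleles")
        object.__setattr__(self, "allele_ids", ids)


# ---------------------------------------------------------------------------
# coordinate conversion
# ---------------------------------------------------------------------------


def _anchor_pos(anchor: str, model: GeneModel) -> int:
    anchor = anchor.lower()
    if anchor == "atg":
        return model.atg_pos
    if anchor == "tss":
        return model.tss_pos
    raise CoordinateError(f"unknown anchor {anchor!r} (use 'atg' or 'tss')")


def convert_coordinate(pos: int, anchor: str, model: GeneModel) -> int:
    """Genomic 1-based position -> signed anchor-relative position (no zero)."""
    lo, hi = model.span
    if not (lo <= pos <= hi):
        raise CoordinateError(f"position {pos} outside reference span {lo}..{hi}")
    a = _anchor_pos(anchor, model)
    return pos - a + 1 if pos >= a else pos - a


def invert_coordinate(rel: int, anchor: str, model: GeneModel) -> int:
    """Signed anchor-relative position -> genomic 1-based position."""
    if rel == 0:
        raise CoordinateError("anchor-relative position 0 does not exist")
    a = _anchor_pos(anchor, model)
    pos = rel + a - 1 if rel > 0 else rel + a
    lo, hi = model.span
    if not (lo <= pos <= hi):
        raise CoordinateError(f"relative position {rel} maps outside span {lo}..{hi}")
    return pos


# ---------------------------------------------------------------------------
# panel I/O
# ---------------------------------------------------------------------------

_META_COLUMNS = ["accession_id", "line_name", "subtype", "flesh_phenotype", "allele_ids"]


def parse_panel(
    fasta_path: str | Path, meta_path: str | Path
) -> tuple[list[AlleleRecord], list[AccessionMeta]]:
    """Read an allele panel: FASTA sequences plus an accession metadata TSV.

    Every FASTA record must be claimed by exactly one accession row, and every
    allele id listed in the metadata must exist in the FASTA.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate allele id {rec.id!r} in {fasta_path}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        logger.warning("empty FASTA %s: returning an empty panel", fasta_path)

    meta_df = pd.read_csv(meta_path, sep="\t", dtype=str, comment="#").fillna("")
    missing_cols = set(_META_COLUMNS) - set(meta_df.columns)
    if missing_cols:
        raise FormatError(f"metadata missing columns: {sorted(missing_cols)}")

    alleles: list[AlleleRecord] = []
    accessions: list[AccessionMeta] = []
    claimed: dict[str, str] = {}
    for row in meta_df.itertuples(index=False):
        acc_id = row.accession_id
        allele_ids = tuple(x for x in str(row.allele_ids).split(",") if x)
        subtype = row.subtype or None
        meta = AccessionMeta(
            accession_id=acc_id,
            line_name=row.line_name,
            observed_flesh=row.flesh_phenotype or "unknown",
            allele_ids=allele_ids,
            subtype=subtype,
        )
        accessions.append(meta)
        for aid in allele_ids:
            if aid not in seqs:
                raise LinkageError(f"accession {acc_id} references missing allele {aid!r}")
            if aid in claimed:
                raise LinkageError(
                    f"allele {aid!r} claimed by both {claimed[aid]} and {acc_id}"
                )
            claimed[aid] = acc_id
            alleles.append(
                AlleleRecord(
                    allele_id=aid,
                    accession_id=acc_id,
                    group=None,
                    subtype=subtype,
                    sequence=seqs[aid],
                )
            )
    orphans = set(seqs) - set(claimed)
    if orphans:
        raise LinkageError(f"alleles not referenced by any accession: {sorted(orphans)}")
    return alleles, accessions


def write_panel(
    alleles: Sequence[AlleleRecord],
    accessions: Sequence[AccessionMeta],
    fasta_path: str | Path,
    meta_path: str | Path,
) -> None:
    records = [
        SeqRecord(Seq(a.sequence), id=a.allele_id, description="") for a in alleles
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "accession_id": m.accession_id,
            "line_name": m.line_name,
            "subtype": m.subtype or "",
            "flesh_phenotype": m.observed_flesh,
            "allele_ids": ",".join(m.allele_ids),
        }
        for m in accessions
    ]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(meta_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene model I/O (GFF3 subset)
# ---------------------------------------------------------------------------


def _parse_attributes(text: str) -> dict[str, str]:
    out = {}
    for chunk in text.strip().split(";"):
        if chunk and "=" in chunk:
            k, v = chunk.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def parse_gene_model(gff_path: str | Path, strict_structure: bool = True) -> GeneModel:
    """Read the GFF3 subset: a ``gene`` line carrying tss_pos/atg_pos attributes,
    plus ``promoter``/``exon``/``intron`` feature lines."""
    features: list[GeneFeature] = []
    counters = {"exon": 0, "intron": 0, "promoter": 0}
    tss = atg = None
    ref_id = None
    for line in Path(gff_path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise FormatError(f"bad GFF3 line (need 9 columns): {line!r}")
        seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
        ref_id = ref_id or seqid
        if ftype == "gene":
            a = _parse_attributes(attrs)
            if "tss_pos" not in a or "atg_pos" not in a:
                raise ModelError("gene record must carry tss_pos and atg_pos attributes")
            tss, atg = int(a["tss_pos"]), int(a["atg_pos"])
        elif ftype in counters:
            counters[ftype] += 1
            features.append(GeneFeature(ftype, counters[ftype], int(start), int(end)))
        else:
            raise FormatError(f"unsupported feature type {ftype!r}")
    if tss is None or atg is None:
        raise ModelError("gene model is missing its TSS/ATG anchors")
    model = GeneModel(
        reference_allele_id=ref_id or "reference",
        features=tuple(sorted(features, key=lambda f: f.start)),
        tss_pos=tss,
        atg_pos=atg,
    )
    return model.validate(strict_structure=strict_structure)


def write_gene_model(model: GeneModel, gff_path: str | Path) -> None:
    lo, hi = model.span
    lines = ["##gff-version 3"]
    lines.append(
        "\t".join(
            [
                model.reference_allele_id,
                "fleshmark",
                "gene",
                str(lo),
                str(hi),
                ".",
                model.strand,
                ".",
                f"ID=gene;tss_pos={model.tss_pos};atg_pos={model.atg_pos}",
            ]
        )
    )
    for f in sorted(model.features, key=lambda f: f.start):
        lines.append(
            "\t".join(
                [
                    model.reference_allele_id,
                    "fleshmark",
                    f.kind,
                    str(f.start),
                    str(f.end),
                    ".",
                    model.strand,
                    ".",
                    f"ID={f.name}",
                ]
            )
        )
    Path(gff_path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# small shared helpers
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def group_of(record: AlleleRecord) -> str | None:
    if record.group:
        return record.group
    if record.subtype in RF_SUBTYPES:
        return "Rf"
    if record.subtype in WF_SUBTYPES:
        return "Wf"
    return None
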