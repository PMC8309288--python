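"""Virtual PCR and band-pattern genotype calls.

Primer annealing is approximated by a mismatch model standing in for a stringent
annealing temperature: a binding site requires an exact match over the
3'-terminal bases (default 3) and at most ``max_mismatch`` mismatches elsewhere
(default 2); N in the template counts as a mismatch.  An amplicon is produced
for every convergent forward/reverse site pair within the allowed size range;
its size is the distance between the two primers' 5' ends, inclusive.

Genotype calls:

* codominant length markers — bands are matched to the expected per-class sizes
  within a gel-resolution tolerance (default +/-2 nt): Rf-size only -> Rf,
  Wf-size only -> Wf, both -> Het, none -> fail;
* dominant allele-specific pairs — product from the Rf-specific pair only -> Rf,
  Wf-specific only -> Wf, both -> Het, neither -> fail.

Concordance compares the marker-predicted flesh colour with the recorded
phenotype; pink/segregating accessions are reported in their own bucket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .io_core import AccessionMeta, AlleleRecord, group_of, revcomp
from .marker_design import PrimerSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingModel:
    max_mismatch: int = 2
    exact_3prime_bases: int = 3


@dataclass(frozen=True)
class BindingSite:
    allele_id: str
    primer_id: str
    strand: str  # '+': primer anneals to the minus strand, extends rightward
    start: int  # 1-based leftmost template position of the footprint
    end: int
    three_prime_pos: int
    mismatches: int

    @property
    def exact_three_prime(self) -> bool:
        return True  # sites violating the 3' requirement are never emitted


def find_binding_sites(
    primer: str,
    template: str,
    model: BindingModel | None = None,
    allele_id: str = "",
    primer_id: str = "",
) -> list[BindingSite]:
    """All annealing sites of a primer on both strands of a template."""
    model = model or BindingModel()
    if len(primer) > len(template):
        logger.warning("primer %s longer than template: no sites", primer_id or primer)
        return []
    bad = set(primer) - set("ACGT")
    if bad:
        raise ValueError(f"primer contains non-ACGT bases: {sorted(bad)}")
    t = np.frombuffer(template.encode(), dtype=np.uint8)
    win = sliding_window_view(t, len(primer))
    sites: list[BindingSite] = []
    k = model.exact_3prime_bases

    p_fwd = np.frombuffer(primer.encode(), dtype=np.uint8)
    ne = win != p_fwd
    hits = np.where((ne.sum(axis=1) <= model.max_mismatch) & ~ne[:, -k:].any(axis=1))[0]
    for i in hits:
        sites.append(
            BindingSite(
                allele_id=allele_id,
                primer_id=primer_id,
                strand="+",
                start=int(i) + 1,
                end=int(i) + len(primer),
                three_prime_pos=int(i) + len(primer),
                mismatches=int(ne[i].sum()),
            )
        )

    p_rev = np.frombuffer(revcomp(primer).encode(), dtype=np.uint8)
    ne = win != p_rev
    # the primer's 3' end corresponds to the leftmost bases of the footprint
    hits = np.where((ne.sum(axis=1) <= model.max_mismatch) & ~ne[:, :k].any(axis=1))[0]
    for i in hits:
        sites.append(
            BindingSite(
                allele_id=allele_id,
                primer_id=primer_id,
                strand="-",
                start=int(i) + 1,
                end=int(i) + len(primer),
                three_prime_pos=int(i) + 1,
                mismatches=int(ne[i].sum()),
            )
        )
    return sites


@dataclass(frozen=True)
class Amplicon:
    size: int
    start: int  # forward primer 5' (template plus-strand coordinates)
    end: int  # reverse primer 5'


def simulate_pcr(
    fw: str,
    rv: str,
    template: str,
    size_range: tuple[int, int] = (50, 5000),
    model: BindingModel | None = None,
    allele_id: str = "",
) -> list[Amplicon]:
    """Amplicons from every convergent pair of binding sites within size range."""
    model = model or BindingModel()
    amplicons: list[Amplicon] = []
    sites_fw = find_binding_sites(fw, template, model, allele_id, "fw")
    sites_rv = find_binding_sites(rv, template, model, allele_id, "rv")
    for a, b in ((sites_fw, sites_rv), (sites_rv, sites_fw)):
        for sf in (s for s in a if s.strand == "+"):
            for sr in (s for s in b if s.strand == "-"):
                if sr.three_prime_pos <= sf.three_prime_pos:
                    continue  # divergent or overlapping orientation
                size = sr.end - sf.start + 1
                if size_range[0] <= size <= size_range[1]:
                    amplicons.append(Amplicon(size=size, start=sf.start, end=sr.end))
    uniq = sorted(set(amplicons), key=lambda x: (x.start, x.end))
    return uniq


def amplify_with_set(
    marker: PrimerSet,
    template: str,
    model: BindingModel | None = None,
    size_range: tuple[int, int] = (50, 5000),
) -> dict[str, list[Amplicon]]:
    """Products per primer pair: key 'band' for length mode, group names for
    allele-specific mode."""
    out: dict[str, list[Amplicon]] = {}
    for key, (fw, rv) in marker.pairs.items():
        out[key] = simulate_pcr(fw.sequence, rv.sequence, template, size_range, model)
    return out


@dataclass
class MarkerCall:
    accession_id: str
    marker_name: str
    bands: dict[str, list[int]]  # allele id -> product sizes (all pairs pooled)
    call: str  # Rf | Wf | Het | fail
    note: str = ""


def call_marker_genotype(
    marker: PrimerSet,
    alleles: Sequence[AlleleRecord],
    model: BindingModel | None = None,
    size_tolerance: int = 2,
) -> MarkerCall:
    """Genotype one accession (1-2 allele sequences) with one marker."""
    if not 1 <= len(alleles) <= 2:
        raise ValueError("an accession carries 1 or 2 alleles")
    accession_id = alleles[0].accession_id
    bands: dict[str, list[int]] = {}
    note = ""

    if marker.mode == "codominant_length":
        exp_rf = marker.expected_sizes.get("Rf")
        exp_wf = marker.expected_sizes.get("Wf")
        if (
            exp_rf is not None
            and exp_wf is not None
            and abs(exp_rf - exp_wf) <= 2 * size_tolerance
        ):
            note = "non-discriminating: expected class sizes within tolerance"
            logger.warning("%s: %s", marker.marker_name, note)
        present: set[str] = set()
        for al in alleles:
            sizes = [
                a.size
                for amps in amplify_with_set(marker, al.sequence, model).values()
                for a in amps
            ]
            bands[al.allele_id] = sorted(sizes)
            for s in sizes:
                if exp_rf is not None and abs(s - exp_rf) <= size_tolerance:
                    present.add("Rf")
                elif exp_wf is not None and abs(s - exp_wf) <= size_tolerance:
                    present.add("Wf")
        call = _pattern_to_call(present)
        if note:
            call = "fail"
    else:  # dominant_allele_specific_pair
        present = set()
        for al in alleles:
            products = amplify_with_set(marker, al.sequence, model)
            sizes = [a.size for amps in products.values() for a in amps]
            bands[al.allele_id] = sorted(sizes)
            for grp in ("Rf", "Wf"):
                if products.get(grp):
                    present.add(grp)
        call = _pattern_to_call(present)
    return MarkerCall(accession_id, marker.marker_name, bands, call, note)


def _pattern_to_call(present: set[str]) -> str:
    if present == {"Rf", "Wf"}:
        return "Het"
    if present == {"Rf"}:
        return "Rf"
    if present == {"Wf"}:
        return "Wf"
    return "fail"


# ---------------------------------------------------------------------------
# panel-level genotyping and concordance
# ---------------------------------------------------------------------------

PHENOTYPE_RULES = ("dominant", "recessive")


def predict_phenotype(call: str, rule: str = "dominant") -> str | None:
    """Marker call -> predicted flesh colour.

    ``dominant``: any Rf allele predicts red (heterozygous commercial F1 red
    cultivars exist); ``recessive``: red only for Rf/Rf homozygotes.
    """
    if rule not in PHENOTYPE_RULES:
        raise ValueError(f"phenotype rule must be one of {PHENOTYPE_RULES}")
    if call == "Rf":
        return "red"
    if call == "Wf":
        return "white"
    if call == "Het":
        return "red" if rule == "dominant" else "white"
    return None  # fail -> uncallable


@dataclass
class ConcordanceReport:
    per_marker: pd.DataFrame  # marker, concordant, discordant, uncallable, segregating, fraction
    discordant: dict[str, list[str]]  # marker -> accession ids

    def fraction(self, marker_name: str) -> float | None:
        row = self.per_marker.set_index("marker").loc[marker_name]
        total = row["concordant"] + row["discordant"]
        return None if total == 0 else row["concordant"] / total


def genotype_panel(
    markers: Sequence[PrimerSet],
    alleles: Sequence[AlleleRecord],
    accessions: Sequence[AccessionMeta],
    phenotype_rule: str = "dominant",
    model: BindingModel | None = None,
    size_tolerance: int = 2,
) -> tuple[list[MarkerCall], ConcordanceReport]:
    by_acc: dict[str, list[AlleleRecord]] = {}
    for al in alleles:
        by_acc.setdefault(al.accession_id, []).append(al)
    calls: list[MarkerCall] = []
    rows = []
    discordant: dict[str, list[str]] = {m.marker_name: [] for m in markers}
    for marker in markers:
        counts = {"concordant": 0, "discordant": 0, "uncallable": 0, "segregating": 0}
        for acc in accessions:
            acc_alleles = by_acc.get(acc.accession_id, [])
            if not acc_alleles:
                counts["uncallable"] += 1
                continue
            call = call_marker_genotype(marker, acc_alleles, model, size_tolerance)
            calls.append(call)
            predicted = predict_phenotype(call.call, phenotype_rule)
            observed = acc.observed_flesh
            if observed in ("pink", "segregating"):
                counts["segregating"] += 1
            elif predicted is None or observed == "unknown":
                counts["uncallable"] += 1
            elif predicted == observed:
                counts["concordant"] += 1
            else:
                counts["discordant"] += 1
                discordant[marker.marker_name].append(acc.accession_id)
        total = counts["concordant"] + counts["discordant"]
        rows.append(
            {
                "marker": marker.marker_name,
                **counts,
                "fraction_concordant": counts["concordant"] / total if total else float("nan"),
            }
        )
    report = ConcordanceReport(per_marker=pd.DataFrame(rows), discordant=discordant)
    return calls, report


def calls_to_frame(calls: Sequence[MarkerCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "accession_id": c.accession_id,
                "marker": c.marker_name,
                "bands": ";".join(
                    f"{aid}:{','.join(map(str, sizes)) or '-'}"
                    for aid, sizes in sorted(c.bands.items())
                ),
                "call": c.call,
                "note": c.note,
            }
        )
    return pd.DataFrame(rows, columns=["accession_id", "marker", "bands", "call", "note"])
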