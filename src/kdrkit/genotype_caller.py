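"""Sequence-based kdr genotyping from Sanger consensus sequences.

Calls SS/RS/RR at each mutation site of a :class:`~kdrkit.reference_model.GeneModel`
from base-called gDNA or cDNA consensus sequences in which heterozygous
positions are encoded as IUPAC ambiguity codes (a double C/T peak becomes
``Y``).  The caller anchors each site's guide sequence on either strand,
extracts the codon at the guide-relative offset and applies the codon rule:

* variable base equal to the wild base            -> SS
* variable base equal to the mutant base          -> RR
* IUPAC code expanding to exactly {wild, mutant}  -> RS
* anything else (other base, wider ambiguity, missing anchor, truncated
  codon, non-variable position not matching the wild codon)
                                                  -> INDETERMINATE

INDETERMINATE is a value, not an error; the only hard failure is an ambiguous
anchor (two equally good guide placements), which is reported per site without
aborting the remaining sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO

from .reference_model import (
    GeneModel,
    Genotype,
    MutationSite,
    expand_base,
    normalize_sequence,
    reverse_complement,
    scan_guide,
    translate_codon,
)

logger = logging.getLogger("kdrkit.genotype_caller")

FORWARD = "forward"
REVCOMP = "reverse-complement"


class AmbiguousAnchorError(ValueError):
    """Two or more equally good guide placements; positions are listed."""

    def __init__(self, site_name: str, positions: Sequence):
        self.site_name = site_name
        self.positions = tuple(positions)
        super().__init__(
            f"ambiguous anchor for {site_name}: equally good matches at "
            f"forward positions {sorted(self.positions)}"
        )


class FastaInputError(IOError):
    """Unreadable or empty FASTA input."""


@dataclass(frozen=True)
class CallOptions:
    """Tunables for anchor search and calling.

    ``max_mismatches`` counts guide mismatches outside the codon footprint
    (codon bases are always masked, so allelic variation under a guide tail is
    free).  Ties between equally good placements are broken by the unmasked
    mismatch count; a residual tie raises :class:`AmbiguousAnchorError`.
    """

    max_mismatches: int = 1
    search_both_strands: bool = True


DEFAULT_OPTIONS = CallOptions()


@dataclass(frozen=True)
class AnchorMatch:
    site_name: str
    position: int       # 0-based start of the guide match on the *forward* query
    strand: str         # FORWARD or REVCOMP
    mismatches: int     # masked (non-codon) mismatch count


@dataclass(frozen=True)
class SiteCall:
    site_name: str
    genotype: Genotype
    observed_codon: Optional[str] = None
    amino_acids: frozenset = frozenset()
    evidence: Optional[AnchorMatch] = None
    note: str = ""


@dataclass
class SequenceReport:
    sequence_id: str
    calls: list = field(default_factory=list)
    input_kind: str = "unknown"  # gDNA | cDNA | unknown

    def call(self, site_name: str) -> SiteCall:
        for c in self.calls:
            if c.site_name == site_name:
                return c
        raise KeyError(site_name)


# ---------------------------------------------------------------------------
# Anchor location
# ---------------------------------------------------------------------------

def locate_anchor(
    query: str,
    site: MutationSite,
    max_mismatches: int = 1,
    search_both_strands: bool = True,
) -> Optional[AnchorMatch]:
    """Best guide placement for ``site`` on ``query`` (either strand), or None.

    Reverse-complement matches report coordinates of the guide footprint on
    the forward query, with the strand flag set.  The unique best match is the
    one with the fewest masked mismatches, ties broken by raw mismatches; an
    unresolved tie raises :class:`AmbiguousAnchorError`.
    """
    if not query:
        raise ValueError("query must be nonempty")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    query = normalize_sequence(query, context="query")
    glen = len(site.guide_sequence)

    candidates = []  # (masked, raw, strand, fwd_position)
    for hit in scan_guide(query, site, max_mismatches):
        candidates.append((hit.masked_mismatches, hit.raw_mismatches, FORWARD, hit.position))
    if search_both_strands:
        rc = reverse_complement(query)
        for hit in scan_guide(rc, site, max_mismatches):
            fwd_pos = len(query) - (hit.position + glen)
            candidates.append((hit.masked_mismatches, hit.raw_mismatches, REVCOMP, fwd_pos))
    if not candidates:
        return None
    best_key = min(c[:2] for c in candidates)
    best = [c for c in candidates if c[:2] == best_key]
    if len(best) > 1:
        raise AmbiguousAnchorError(site.name, [c[3] for c in best])
    masked, _raw, strand, pos = best[0]
    return AnchorMatch(site_name=site.name, position=pos, strand=strand, mismatches=masked)


# ---------------------------------------------------------------------------
# Codon classification
# ---------------------------------------------------------------------------

def classify_codon(site: MutationSite, codon: str) -> Genotype:
    """Apply the genotype rule to an observed (possibly ambiguous) codon."""
    codon = normalize_sequence(codon, context="observed codon")
    if len(codon) != 3:
        return Genotype.INDETERMINATE
    vp = site.variable_position - 1
    for i in range(3):
        if i == vp:
            continue
        # non-variable positions must be exactly the wild base
        if expand_base(codon[i]) != expand_base(site.wild_codon[i]):
            return Genotype.INDETERMINATE
    obs = expand_base(codon[vp])
    if obs == expand_base(site.wild_base):
        return Genotype.SS
    if obs == expand_base(site.mutant_base):
        return Genotype.RR
    if obs == frozenset({site.wild_base, site.mutant_base}):
        return Genotype.RS
    return Genotype.INDETERMINATE


def call_site(
    query: str,
    site: MutationSite,
    options: CallOptions = DEFAULT_OPTIONS,
) -> SiteCall:
    """Genotype one site on one consensus sequence."""
    query = normalize_sequence(query, context="query")
    anchor = locate_anchor(
        query, site,
        max_mismatches=options.max_mismatches,
        search_both_strands=options.search_both_strands,
    )
    if anchor is None:
        return SiteCall(site.name, Genotype.INDETERMINATE, note="anchor not found")

    # extract the codon in coding orientation
    oriented = query if anchor.strand == FORWARD else reverse_complement(query)
    start = (
        anchor.position if anchor.strand == FORWARD
        else len(query) - (anchor.position + len(site.guide_sequence))
    )
    codon_start = start + len(site.guide_sequence) + site.codon_offset
    codon = oriented[codon_start : codon_start + 3]
    if len(codon) < 3 or codon_start < 0:
        return SiteCall(
            site.name, Genotype.INDETERMINATE, evidence=anchor, note="codon truncated"
        )
    genotype = classify_codon(site, codon)
    return SiteCall(
        site_name=site.name,
        genotype=genotype,
        observed_codon=codon,
        amino_acids=translate_codon(codon),
        evidence=anchor,
    )


# ---------------------------------------------------------------------------
# Whole-sequence and FASTA level
# ---------------------------------------------------------------------------

def _coding_position(query_len: int, anchor: AnchorMatch, guide_len: int) -> int:
    """Anchor start in coding orientation (for distance measurements)."""
    if anchor.strand == FORWARD:
        return anchor.position
    return query_len - (anchor.position + guide_len)


def _infer_input_kind(model: GeneModel, query_len: int, calls: Sequence) -> str:
    """gDNA vs cDNA from the spacing between the 918/929 block and the 1014 block."""
    if model.intron_spec is None:
        return "unknown"
    intron_pos, intron_len = model.intron_spec
    upstream = next(
        (c for c in calls
         if c.evidence is not None and model.site(c.site_name).codon_number < 1000),
        None,
    )
    downstream = next(
        (c for c in calls
         if c.evidence is not None and model.site(c.site_name).codon_number >= 1000),
        None,
    )
    if upstream is None or downstream is None:
        return "unknown"
    up_site = model.site(upstream.site_name)
    down_site = model.site(downstream.site_name)
    d = abs(
        _coding_position(query_len, downstream.evidence, len(down_site.guide_sequence))
        - _coding_position(query_len, upstream.evidence, len(up_site.guide_sequence))
    )
    if model.reference_sequence is not None:
        expected = abs(
            scan_guide(model.reference_sequence, down_site, 0)[0].position
            - scan_guide(model.reference_sequence, up_site, 0)[0].position
        )
    else:
        expected = None
    if expected is not None:
        if abs(d - expected) <= 100:
            return "cDNA"
        if d >= expected + 0.9 * intron_len:
            return "gDNA"
        return "unknown"
    return "gDNA" if d >= intron_len else "cDNA"


def call_all_sites(
    query: str,
    model: GeneModel,
    options: CallOptions = DEFAULT_OPTIONS,
    sequence_id: str = "",
    sites: Optional[Sequence] = None,
) -> SequenceReport:
    """One :class:`SiteCall` per site; ambiguity errors are confined to their site."""
    query = normalize_sequence(query, context="query")
    selected = list(model.sites)
    if sites is not None:
        selected = [model.site(n) for n in sites]
    if not selected:
        raise ValueError("model/site selection has no sites")
    calls = []
    for site in selected:
        try:
            calls.append(call_site(query, site, options))
        except AmbiguousAnchorError as exc:
            logger.warning("%s: %s", sequence_id or "<sequence>", exc)
            calls.append(
                SiteCall(site.name, Genotype.INDETERMINATE, note=str(exc))
            )
    report = SequenceReport(sequence_id=sequence_id, calls=calls)
    report.input_kind = _infer_input_kind(model, len(query), calls)
    return report


REPORT_COLUMNS = (
    "sequence_id", "site", "codon", "genotype", "amino_acids",
    "strand", "anchor_position", "mismatches", "input_kind", "note",
)


def reports_to_frame(reports: Sequence) -> pd.DataFrame:
    """Flatten reports to one row per (sequence, site); positions are 1-based."""
    rows = []
    for rep in reports:
        for c in rep.calls:
            rows.append({
                "sequence_id": rep.sequence_id,
                "site": c.site_name,
                "codon": c.observed_codon or "",
                "genotype": c.genotype.value,
                "amino_acids": "/".join(sorted(c.amino_acids)),
                "strand": c.evidence.strand if c.evidence else "",
                "anchor_position": c.evidence.position + 1 if c.evidence else "",
                "mismatches": c.evidence.mismatches if c.evidence else "",
                "input_kind": rep.input_kind,
                "note": c.note,
            })
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def genotype_fasta(
    path: Union[str, Path],
    model: GeneModel,
    options: CallOptions = DEFAULT_OPTIONS,
    sites: Optional[Sequence] = None,
    output_csv: Optional[Union[str, Path]] = None,
) -> pd.DataFrame:
    """Genotype every record of a FASTA file; optionally write the call CSV."""
    path = Path(path)
    if not path.exists():
        raise FastaInputError(f"FASTA not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaInputError(f"no FASTA records in {path}")

    seen = {}
    reports = []
    for rec in records:
        rec_id = rec.id
        if rec_id in seen:
            seen[rec_id] += 1
            new_id = f"{rec_id}__{seen[rec_id]}"
            warnings.warn(
                f"duplicate FASTA id {rec_id!r}; renamed to {new_id!r}", stacklevel=2
            )
            rec_id = new_id
        else:
            seen[rec_id] = 1
        reports.append(
            call_all_sites(str(rec.seq), model, options, sequence_id=rec_id, sites=sites)
        )
    frame = reports_to_frame(reports)
    if output_csv is not None:
        frame.to_csv(output_csv, index=False)
    return frame
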