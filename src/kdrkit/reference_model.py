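"""Gene model for VSSC target-site resistance genotyping.

The voltage-sensitive sodium channel (VSSC, *para*-like) of the house fly is
the target of pyrethroid insecticides; point mutations in it (knockdown
resistance, *kdr*) reduce insecticide binding. This module holds the codon-level
description of the four canonical mutation sites (M918T, T929I, L1014F and
L1014H), the guide-anchor sequences used to pinpoint each codon in a sequenced
fragment, IUPAC-aware codon translation, and the structured-text (YAML) config
round trip.

Conventions
-----------
* Sequences are handled case-insensitively; ``U`` is accepted and mapped to
  ``T``. Internally everything is upper-case DNA.
* ``codon_offset`` is the signed position of the codon's first base relative to
  the *end* (exclusive) of the guide match on the coding strand. Offset 0 means
  the codon starts immediately after the guide; negative offsets mean the codon
  overlaps the guide's 3' tail (the packaged L1014F guide ends on the codon's
  variable base, so it carries offset -1).
* Guide/anchor mismatch counting masks codon positions, so a guide that spells
  one allelic variant still anchors sequences of every genotype.
"""

from __future__ import annotations

import enum
import importlib.resources
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import yaml
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq


class GeneModelError(ValueError):
    """Base class for gene-model problems."""


class ConfigError(GeneModelError):
    """Malformed gene-model configuration; message names the offending field."""


class ConsistencyError(GeneModelError):
    """Config is well-formed but internally inconsistent (e.g. guide absent)."""


class SequenceInputError(ValueError):
    """A sequence argument contains characters outside the IUPAC alphabet."""


# ---------------------------------------------------------------------------
# IUPAC machinery
# ---------------------------------------------------------------------------

#: letter -> frozenset of unambiguous bases it stands for (X and N both = ACGT)
IUPAC_EXPANSION: Mapping[str, frozenset] = {
    letter.upper(): frozenset(bases)
    for letter, bases in ambiguous_dna_values.items()
}

#: frozenset of bases -> the single IUPAC letter encoding exactly that set
IUPAC_FOR_SET: Mapping[frozenset, str] = {
    frozenset(bases): letter.upper()
    for letter, bases in ambiguous_dna_values.items()
    if letter.upper() != "X"  # X duplicates N
}

UNAMBIGUOUS = frozenset("ACGT")


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Upper-case, map U->T and validate against the IUPAC DNA alphabet."""
    out = str(seq).strip().upper().replace("U", "T")
    bad = set(out) - set(IUPAC_EXPANSION)
    if bad:
        raise SequenceInputError(
            f"{context} contains non-IUPAC characters: {sorted(bad)!r}"
        )
    return out


def expand_base(base: str) -> frozenset:
    """Set of unambiguous bases an IUPAC letter stands for."""
    b = base.upper().replace("U", "T")
    try:
        return IUPAC_EXPANSION[b]
    except KeyError:
        raise SequenceInputError(f"not an IUPAC nucleotide code: {base!r}") from None


def bases_compatible(a: str, b: str) -> bool:
    """True when the two (possibly ambiguous) bases share at least one expansion."""
    return bool(expand_base(a) & expand_base(b))


def iupac_for(bases: Iterable) -> str:
    """IUPAC letter encoding exactly the given set of unambiguous bases."""
    key = frozenset(bases)
    try:
        return IUPAC_FOR_SET[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(key)!r}") from None


def translate_codon(codon: str) -> frozenset:
    """Translate a 3-mer that may contain IUPAC ambiguity codes.

    Returns the set of one-letter amino acids (``*`` for stop) obtained by
    expanding every ambiguity code and translating each expansion with the
    standard genetic code.  ``YTT`` therefore yields ``{L, F}`` — the logic
    behind heterozygote (RS) calls from Sanger consensus sequences.
    """
    codon = normalize_sequence(codon, context="codon")
    if len(codon) != 3:
        raise ValueError(f"codon must have length 3, got {codon!r}")
    expansions = [sorted(expand_base(b)) for b in codon]
    return frozenset(
        str(Seq("".join(triplet)).translate()) for triplet in itertools.product(*expansions)
    )


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

class Genotype(enum.Enum):
    """Diploid genotype at one kdr site (closed enumeration)."""

    SS = "SS"  # sus/sus
    RS = "RS"  # kdr/sus
    RR = "RR"  # kdr/kdr
    INDETERMINATE = "INDETERMINATE"

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.value


@dataclass(frozen=True)
class MutationSite:
    """One kdr mutation: codon-level definition plus its guide anchor."""

    name: str
    codon_number: int
    wild_aa: str
    mutant_aa: str
    wild_codon: str
    mutant_codon: str
    guide_sequence: str
    codon_offset: int
    variable_position: int  # 1-based index of the codon base that differs

    def __post_init__(self) -> None:
        object.__setattr__(self, "wild_codon", normalize_sequence(self.wild_codon, context="wild_codon"))
        object.__setattr__(self, "mutant_codon", normalize_sequence(self.mutant_codon, context="mutant_codon"))
        object.__setattr__(self, "guide_sequence", normalize_sequence(self.guide_sequence, context="guide_sequence"))
        if not self.name:
            raise ConfigError("name: must be nonempty")
        if self.codon_number <= 0:
            raise ConfigError(f"codon_number: must be positive, got {self.codon_number}")
        for fld in ("wild_codon", "mutant_codon"):
            codon = getattr(self, fld)
            if len(codon) != 3 or set(codon) - set("ACGT"):
                raise ConfigError(f"{fld}: must be an unambiguous 3-mer, got {codon!r}")
        diffs = [i + 1 for i in range(3) if self.wild_codon[i] != self.mutant_codon[i]]
        if len(diffs) != 1:
            raise ConfigError(
                f"wild_codon/mutant_codon: must differ at exactly one position "
                f"({self.wild_codon} vs {self.mutant_codon} differ at {diffs})"
            )
        if self.variable_position not in (1, 2, 3):
            raise ConfigError(f"variable_position: must be 1, 2 or 3, got {self.variable_position}")
        if diffs[0] != self.variable_position:
            raise ConfigError(
                f"variable_position: codons differ at position {diffs[0]}, "
                f"not declared position {self.variable_position}"
            )
        if translate_codon(self.wild_codon) != frozenset(self.wild_aa.upper()):
            raise ConfigError(f"wild_aa: {self.wild_codon} does not encode {self.wild_aa}")
        if translate_codon(self.mutant_codon) != frozenset(self.mutant_aa.upper()):
            raise ConfigError(f"mutant_aa: {self.mutant_codon} does not encode {self.mutant_aa}")
        if not self.guide_sequence or set(self.guide_sequence) - set("ACGT"):
            raise ConfigError("guide_sequence: must be nonempty and unambiguous")

    @property
    def wild_base(self) -> str:
        return self.wild_codon[self.variable_position - 1]

    @property
    def mutant_base(self) -> str:
        return self.mutant_codon[self.variable_position - 1]

    @property
    def het_code(self) -> str:
        """IUPAC code for a heterozygote at the variable position (e.g. Y for C/T)."""
        return iupac_for({self.wild_base, self.mutant_base})

    def guide_codon_mask(self) -> frozenset:
        """Guide-relative indices that fall on the codon (excluded from mismatch counts)."""
        n = len(self.guide_sequence)
        start = n + self.codon_offset
        return frozenset(i for i in range(start, start + 3) if 0 <= i < n)


def mutation_call_label(site: MutationSite, genotype: Genotype) -> str:
    """Human-readable call label, e.g. ``L1014F hom-resistant`` / ``L1014 wild-type``."""
    if genotype is Genotype.INDETERMINATE:
        raise ValueError("no label for INDETERMINATE calls")
    if genotype is Genotype.RR:
        return f"{site.name} hom-resistant"
    if genotype is Genotype.RS:
        return f"{site.name} het"
    return f"{site.wild_aa}{site.codon_number} wild-type"


# ---------------------------------------------------------------------------
# Guide scanning (shared by model validation and the genotype caller)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GuideHit:
    """One candidate guide placement on a query (single strand)."""

    position: int       # 0-based start in the scanned sequence
    masked_mismatches: int  # mismatches outside the codon footprint
    raw_mismatches: int     # mismatches including codon positions


def scan_guide(query: str, site: MutationSite, max_mismatches: int) -> list:
    """All windows where the guide matches with <= max_mismatches masked mismatches.

    Comparison is IUPAC-aware (an ambiguity code in the query matches a guide
    base contained in its expansion); positions covered by the mutation codon
    are masked so allelic variation under the guide tail never costs a mismatch.
    """
    guide = site.guide_sequence
    mask = site.guide_codon_mask()
    n, m = len(query), len(guide)
    hits = []
    for s in range(n - m + 1):
        raw = masked = 0
        window = query[s : s + m]
        for i, (gb, qb) in enumerate(zip(guide, window)):
            if gb == qb:
                continue
            if not bases_compatible(gb, qb):
                raw += 1
                if i not in mask:
                    masked += 1
                    if masked > max_mismatches:
                        break
            # compatible-but-unequal (ambiguity overlap) counts as a match
        else:
            hits.append(GuideHit(position=s, masked_mismatches=masked, raw_mismatches=raw))
    return hits


# ---------------------------------------------------------------------------
# GeneModel
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """The VSSC gene model: sites, optional reference sequence and PASA config."""

    gene_name: str
    sites: Sequence
    reference_labels: Sequence = field(default_factory=tuple)
    reference_sequence: Optional[str] = None  # coding strand, cDNA form
    intron_spec: Optional[tuple] = None       # (position on cDNA, length)
    pasa: Optional[object] = None             # kdrkit.pasa.AssayDefinition
    schema_version: int = 1

    def __post_init__(self) -> None:
        if self.reference_sequence is not None:
            self.reference_sequence = normalize_sequence(
                self.reference_sequence, context="reference_sequence"
            )
        self.validate()

    def validate(self) -> None:
        names = [s.name for s in self.sites]
        if len(names) != len(set(names)):
            raise ConfigError(f"sites: duplicate site names in {names}")
        if self.intron_spec is not None:
            pos, length = self.intron_spec
            if pos < 0 or length <= 0:
                raise ConfigError(f"intron: invalid (position, length) = {self.intron_spec}")
        if self.reference_sequence is not None:
            for site in self.sites:
                exact = [h for h in scan_guide(self.reference_sequence, site, 0)]
                if len(exact) != 1:
                    raise ConsistencyError(
                        f"guide for {site.name} occurs {len(exact)} times in the "
                        "reference sequence (expected exactly once on the coding strand)"
                    )

    def site(self, name: str) -> MutationSite:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(f"no site named {name!r} in model {self.gene_name}")

    def codon_start(self, site_name: str) -> int:
        """0-based start of a site's codon on the cDNA reference."""
        if self.reference_sequence is None:
            raise GeneModelError("model has no reference sequence")
        site = self.site(site_name)
        hit = scan_guide(self.reference_sequence, site, 0)[0]
        return hit.position + len(site.guide_sequence) + site.codon_offset


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_SITE_FIELDS = (
    "name", "codon_number", "wild_aa", "mutant_aa", "wild_codon",
    "mutant_codon", "guide_sequence", "codon_offset", "variable_position",
)


def _build_site(raw: Mapping, index: int) -> MutationSite:
    missing = [f for f in _SITE_FIELDS if f not in raw]
    if missing:
        raise ConfigError(f"sites[{index}]: missing field(s) {missing}")
    try:
        return MutationSite(**{f: raw[f] for f in _SITE_FIELDS})
    except (ConfigError, SequenceInputError) as exc:
        raise ConfigError(f"sites[{index}].{exc}") from exc


def load_gene_model(
    source: Union[str, Path, Mapping],
    *,
    reference_sequence: Optional[str] = None,
    attach_default_reference: bool = False,
) -> GeneModel:
    """Load and validate a gene model from YAML (path) or an equivalent mapping.

    ``reference_sequence`` optionally attaches a coding-strand cDNA sequence on
    which every guide must occur exactly once.  ``attach_default_reference``
    instead attaches the packaged synthetic reference (see
    :func:`kdrkit.synthetic.reference_layout`).
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"gene model config not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigError("config: top level must be a mapping")
    version = doc.get("schema_version", 1)
    if version != 1:
        raise ConfigError(f"schema_version: unsupported version {version!r} (expected 1)")
    raw_sites = doc.get("sites")
    if not raw_sites:
        raise ConfigError("sites: at least one mutation site is required")
    sites = tuple(_build_site(s, i) for i, s in enumerate(raw_sites))

    intron = doc.get("intron")
    intron_spec = None
    if intron is not None:
        try:
            intron_spec = (int(intron["position"]), int(intron["length"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"intron: needs integer position and length ({exc})") from exc

    assay = None
    if doc.get("pasa") is not None:
        from . import pasa as _pasa  # deferred: pasa imports this module

        assay = _pasa.AssayDefinition.from_config(doc["pasa"])

    if attach_default_reference:
        if reference_sequence is not None:
            raise ConfigError("reference_sequence: given twice (explicit and default)")
        from . import synthetic as _synthetic  # deferred

        reference_sequence = _synthetic.reference_layout().cdna

    return GeneModel(
        gene_name=doc.get("gene_name", "Vssc"),
        reference_labels=tuple(doc.get("reference_labels", ())),
        sites=sites,
        reference_sequence=reference_sequence,
        intron_spec=intron_spec,
        pasa=assay,
        schema_version=version,
    )


def gene_model_to_dict(model: GeneModel, *, include_reference: bool = False) -> dict:
    """Plain-dict form of a model, suitable for YAML dumping and reloading."""
    doc = {
        "schema_version": model.schema_version,
        "gene_name": model.gene_name,
        "reference_labels": list(model.reference_labels),
        "sites": [
            {f: getattr(s, f) for f in _SITE_FIELDS}
            for s in model.sites
        ],
    }
    if model.intron_spec is not None:
        doc["intron"] = {"position": model.intron_spec[0], "length": model.intron_spec[1]}
    if model.pasa is not None:
        doc["pasa"] = model.pasa.to_config()
    if include_reference and model.reference_sequence is not None:
        doc["reference_sequence"] = model.reference_sequence
    return doc


def dump_gene_model(model: GeneModel, path: Union[str, Path]) -> None:
    """Write a model back to YAML; reloading reproduces an identical model."""
    doc = gene_model_to_dict(model, include_reference=False)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def packaged_config_path() -> Path:
    """Path to the packaged default gene-model config."""
    return Path(importlib.resources.files("kdrkit") / "data" / "vssc_model.yaml")


def default_gene_model(*, with_reference: bool = True) -> GeneModel:
    """The packaged four-site VSSC model (optionally with the synthetic reference)."""
    return load_gene_model(packaged_config_path(), attach_default_reference=with_reference)
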