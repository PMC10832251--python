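"""In-silico PASA: allele-specific PCR simulation and gel-pattern genotyping.

PASA (PCR Amplification of Specific Alleles) genotypes the L1014F kdr mutation
with three reactions per insect: a control pair (kdr1+kdr4, nominal 480 bp), a
susceptible-specific pair (kdr1+kdr3, 200 bp) and a resistant-specific pair
(kdr2+kdr4, 280 bp).  Allele discrimination is modeled purely by the textbook
PASA mechanism: a primer can prime synthesis only when its 3'-terminal base(s)
match the template exactly, so the allele-specific primers — whose 3' ends sit
on the codon-1014 variable base — extend on one allele only.  Thermodynamics
are not modeled.

The primer table labels kdr2 "reverse" and kdr3 "forward", but the published
reaction pairing requires each pair to contain opposite-facing primers; the
simulator trusts geometry over labels and reports a primer's effective
orientation as whichever one yields a priming site (the discrepancy is logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .reference_model import Genotype, normalize_sequence, reverse_complement

logger = logging.getLogger("kdrkit.pasa")

GENOTYPE_BAND_ROLES = {
    Genotype.SS: ("control", "susceptible"),
    Genotype.RS: ("control", "susceptible", "resistant"),
    Genotype.RR: ("control", "resistant"),
}


class AssayConfigError(ValueError):
    """Malformed assay definition."""


class AssayGeometryError(ValueError):
    """Primer pair geometry cannot yield a sensible amplicon."""


@dataclass(frozen=True)
class Primer:
    """A PCR primer, written 5'->3'; annealing temperature is metadata only."""

    name: str
    sequence: str
    declared_direction: str = "forward"  # forward | reverse (label from the bench)
    annealing_temp: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", normalize_sequence(self.sequence, context=f"primer {self.name}")
        )
        if not self.sequence or set(self.sequence) - set("ACGT"):
            raise AssayConfigError(
                f"primer {self.name}: sequence must be nonempty and unambiguous"
            )
        if self.declared_direction not in ("forward", "reverse"):
            raise AssayConfigError(
                f"primer {self.name}: direction must be forward/reverse, "
                f"got {self.declared_direction!r}"
            )


@dataclass(frozen=True)
class BindingRules:
    """What counts as a primable site.

    ``three_prime_exact`` 3'-terminal bases must match the template exactly
    (the allele-discrimination mechanism); at most ``max_internal_mismatches``
    are tolerated elsewhere in the footprint.
    """

    three_prime_exact: int = 1
    max_internal_mismatches: int = 0


DEFAULT_RULES = BindingRules()


@dataclass(frozen=True)
class BindingSite:
    primer_name: str
    start: int          # 0-based footprint start on the template coding strand
    end: int            # exclusive footprint end
    orientation: str    # forward | reverse (effective, from geometry)
    mismatches: int     # internal mismatch count


@dataclass(frozen=True)
class Reaction:
    name: str                  # control | susceptible | resistant
    primer_names: tuple
    expected_size: int

    def __post_init__(self) -> None:
        if self.expected_size <= 0:
            raise AssayConfigError(f"reaction {self.name}: expected_size must be positive")
        if len(self.primer_names) != 2:
            raise AssayConfigError(f"reaction {self.name}: needs exactly two primers")


@dataclass(frozen=True)
class AssayDefinition:
    """The three-reaction PASA assay: primer pairs, expected sizes, tolerances."""

    primers: Mapping
    reactions: tuple
    size_tolerance: float = 0.10
    max_product_length: int = 1000
    rules: BindingRules = DEFAULT_RULES

    def __post_init__(self) -> None:
        sizes = [r.expected_size for r in self.reactions]
        if len(set(sizes)) != len(sizes):
            raise AssayConfigError(f"expected sizes must be distinct, got {sizes}")
        names = {r.name for r in self.reactions}
        missing = {"control", "susceptible", "resistant"} - names
        if missing:
            raise AssayConfigError(f"missing reaction(s): {sorted(missing)}")
        if not 0 <= self.size_tolerance < 1:
            raise AssayConfigError("size_tolerance must be a fraction in [0, 1)")
        for r in self.reactions:
            for p in r.primer_names:
                if p not in self.primers:
                    raise AssayConfigError(f"reaction {r.name}: unknown primer {p!r}")

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(name)

    def expected_size(self, role: str) -> int:
        return self.reaction(role).expected_size

    @classmethod
    def from_config(cls, cfg: Mapping) -> "AssayDefinition":
        try:
            primers = {
                p["name"]: Primer(
                    name=p["name"],
                    sequence=p["sequence"],
                    declared_direction=p.get("direction", "forward"),
                    annealing_temp=p.get("annealing_temp"),
                )
                for p in cfg["primers"]
            }
            reactions = tuple(
                Reaction(
                    name=r["name"],
                    primer_names=tuple(r["primers"]),
                    expected_size=int(r["expected_size"]),
                )
                for r in cfg["reactions"]
            )
        except (KeyError, TypeError) as exc:
            raise AssayConfigError(f"pasa: missing or malformed field ({exc})") from exc
        return cls(
            primers=primers,
            reactions=reactions,
            size_tolerance=float(cfg.get("size_tolerance", 0.10)),
            max_product_length=int(cfg.get("max_product_length", 1000)),
        )

    def to_config(self) -> dict:
        return {
            "size_tolerance": self.size_tolerance,
            "max_product_length": self.max_product_length,
            "primers": [
                {
                    "name": p.name,
                    "sequence": p.sequence,
                    "direction": p.declared_direction,
                    "annealing_temp": p.annealing_temp,
                }
                for p in self.primers.values()
            ],
            "reactions": [
                {
                    "name": r.name,
                    "primers": list(r.primer_names),
                    "expected_size": r.expected_size,
                }
                for r in self.reactions
            ],
        }


@dataclass(frozen=True)
class BandPattern:
    """Observed or predicted gel bands (bp) for one insect."""

    insect_id: str
    band_sizes: frozenset

    def __post_init__(self) -> None:
        sizes = frozenset(int(s) for s in self.band_sizes)
        if any(s <= 0 for s in sizes):
            raise ValueError(f"band sizes must be positive, got {sorted(sizes)}")
        object.__setattr__(self, "band_sizes", sizes)


@dataclass(frozen=True)
class DiploidTemplate:
    """The two chromosome copies of one insect (coding-strand sequences)."""

    insect_id: str
    haplotype_a: str
    haplotype_b: str

    def __post_init__(self) -> None:
        for fld in ("haplotype_a", "haplotype_b"):
            seq = normalize_sequence(getattr(self, fld), context=fld)
            if not seq:
                raise ValueError(f"{fld} must be nonempty")
            object.__setattr__(self, fld, seq)

    @property
    def haplotypes(self) -> tuple:
        return (self.haplotype_a, self.haplotype_b)


# ---------------------------------------------------------------------------
# Primer binding
# ---------------------------------------------------------------------------

def _scan_exactish(template: str, probe: str, exact_idx: range, max_internal: int):
    """Footprints where ``probe`` matches: positions in ``exact_idx`` exactly,
    at most ``max_internal`` mismatches elsewhere."""
    n, m = len(template), len(probe)
    exact = set(exact_idx)
    for s in range(n - m + 1):
        internal = 0
        ok = True
        for i in range(m):
            if template[s + i] == probe[i]:
                continue
            if i in exact:
                ok = False
                break
            internal += 1
            if internal > max_internal:
                ok = False
                break
        if ok:
            yield s, internal


def find_binding_sites(
    template: str,
    primer: Primer,
    rules: BindingRules = DEFAULT_RULES,
) -> list:
    """All sites where the primer can prime synthesis, on both strands.

    A forward site is a footprint on the coding strand read 5'->3' as the
    primer; a reverse site is a footprint whose reverse complement reads as the
    primer, i.e. the primer anneals to the coding strand and extends leftwards.
    The primer's 3'-terminal bases (``rules.three_prime_exact`` of them) must
    match exactly — for a reverse site these are the *leftmost* footprint
    positions.
    """
    template = normalize_sequence(template, context="template")
    m = len(primer.sequence)
    k = min(rules.three_prime_exact, m)
    sites = []
    # forward: primer == template[s:s+m], 3' end at the right edge
    for s, internal in _scan_exactish(
        template, primer.sequence, range(m - k, m), rules.max_internal_mismatches
    ):
        sites.append(BindingSite(primer.name, s, s + m, "forward", internal))
    # reverse: revcomp(primer) == template[s:s+m], 3' end at the left edge
    rc = reverse_complement(primer.sequence)
    for s, internal in _scan_exactish(
        template, rc, range(0, k), rules.max_internal_mismatches
    ):
        sites.append(BindingSite(primer.name, s, s + m, "reverse", internal))
    for site in sites:
        if site.orientation != primer.declared_direction:
            logger.debug(
                "primer %s labeled %s but primes in %s orientation at %d "
                "(geometry trusted over label)",
                primer.name, primer.declared_direction, site.orientation, site.start,
            )
    return sites


# ---------------------------------------------------------------------------
# Band prediction and interpretation
# ---------------------------------------------------------------------------

def _products_on_haplotype(
    haplotype: str, p1: Primer, p2: Primer, assay: AssayDefinition
) -> set:
    """Amplicon sizes (end-to-end inclusive) for one primer pair on one haplotype."""
    sites1 = find_binding_sites(haplotype, p1, assay.rules)
    sites2 = find_binding_sites(haplotype, p2, assay.rules)
    products = set()
    pairs = [(sites1, sites2), (sites2, sites1)]
    for fwd_pool, rev_pool in pairs:
        for f in (s for s in fwd_pool if s.orientation == "forward"):
            for r in (s for s in rev_pool if s.orientation == "reverse"):
                size = r.end - f.start
                if size <= 0:
                    continue  # primers facing away from each other: no product
                if f.end > r.start:
                    raise AssayGeometryError(
                        f"primers {f.primer_name}/{r.primer_name} overlap "
                        f"({f.start}-{f.end} vs {r.start}-{r.end})"
                    )
                if size <= assay.max_product_length:
                    products.add(size)
    return products


def predict_bands(template: DiploidTemplate, assay: AssayDefinition) -> BandPattern:
    """Union over haplotypes and reactions of all predicted product sizes."""
    sizes = set()
    for reaction in assay.reactions:
        p1, p2 = (assay.primers[n] for n in reaction.primer_names)
        for hap in template.haplotypes:
            sizes |= _products_on_haplotype(hap, p1, p2, assay)
    return BandPattern(insect_id=template.insect_id, band_sizes=frozenset(sizes))


def match_band(size: int, assay: AssayDefinition) -> Optional[str]:
    """Role (control/susceptible/resistant) whose expected size the band matches."""
    matches = [
        (abs(size - r.expected_size), r.name)
        for r in assay.reactions
        if abs(size - r.expected_size) <= assay.size_tolerance * r.expected_size
    ]
    if not matches:
        return None
    return min(matches)[1]


def genotype_from_bands(pattern: BandPattern, assay: AssayDefinition) -> Genotype:
    """Interpret a gel band pattern.

    Control band (nominal 480 bp) plus the 280-bp band only -> RR; control plus
    200 bp only -> SS; control plus both -> RS.  Without a control band the
    reaction failed and the call is INDETERMINATE regardless of other bands.
    Bands matching no expected size (within tolerance) are ignored with a
    warning.
    """
    roles = set()
    for size in sorted(pattern.band_sizes):
        role = match_band(size, assay)
        if role is None:
            warnings.warn(
                f"{pattern.insect_id or 'pattern'}: band {size} bp matches no "
                f"expected size within ±{assay.size_tolerance:.0%}; ignored",
                stacklevel=2,
            )
        else:
            roles.add(role)
    if "control" not in roles:
        return Genotype.INDETERMINATE
    has_res = "resistant" in roles
    has_sus = "susceptible" in roles
    if has_res and has_sus:
        return Genotype.RS
    if has_res:
        return Genotype.RR
    if has_sus:
        return Genotype.SS
    return Genotype.INDETERMINATE  # control only: both allele reactions failed


def bands_for_genotype(genotype: Genotype, assay: AssayDefinition) -> frozenset:
    """Expected band set for a genotype (inverse of the interpretation table)."""
    if genotype not in GENOTYPE_BAND_ROLES:
        raise ValueError(f"no expected band set for genotype {genotype}")
    return frozenset(
        assay.expected_size(role) for role in GENOTYPE_BAND_ROLES[genotype]
    )


# ---------------------------------------------------------------------------
# CSV plumbing
# ---------------------------------------------------------------------------

def read_band_patterns(path) -> list:
    """Read band patterns from CSV with columns insect_id, band_sizes.

    ``band_sizes`` holds comma-separated sizes inside one (quoted) field, e.g.
    ``"480,200"``; an empty field means no bands.
    """
    import pandas as pd

    frame = pd.read_csv(path, comment="#", dtype=str).fillna("")
    for col in ("insect_id", "band_sizes"):
        if col not in frame.columns:
            raise AssayConfigError(f"band pattern CSV: missing column {col!r}")
    patterns = []
    for _, row in frame.iterrows():
        raw = str(row["band_sizes"]).strip()
        sizes = [int(tok) for tok in raw.replace(";", ",").split(",") if tok.strip()]
        patterns.append(BandPattern(insect_id=row["insect_id"], band_sizes=frozenset(sizes)))
    return patterns


def genotype_patterns(patterns: Sequence, assay: AssayDefinition):
    """Genotype a list of band patterns; returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for pat in patterns:
        genotype = genotype_from_bands(pat, assay)
        matched = sorted(
            s for s in pat.band_sizes if match_band(s, assay) is not None
        )
        rows.append({
            "insect_id": pat.insect_id,
            "band_sizes": ",".join(str(s) for s in sorted(pat.band_sizes)),
            "matched_bands": ",".join(str(s) for s in matched),
            "genotype": genotype.value,
        })
    return pd.DataFrame(rows, columns=["insect_id", "band_sizes", "matched_bands", "genotype"])
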