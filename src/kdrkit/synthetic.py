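"""Synthetic fixtures: genotypes, VSSC sequences, PASA templates, bioassays.

Everything the pipeline consumes can be generated here with no download:

* diploid genotype samples drawn under (or deviating from) Hardy-Weinberg
  equilibrium, parameterized by a kdr allele frequency and an inbreeding-style
  coefficient F;
* consensus sequences (gDNA with a ~1700-bp intron, or intron-free cDNA)
  carrying the four kdr mutations, with heterozygotes rendered as IUPAC codes;
* per-chromosome haplotype pairs for the in-silico PASA assay;
* bottle-bioassay mortality curves (monotone, logistic in time) for
  susceptible and resistant populations;
* the packaged worked-example tables: the 19-location Abu Dhabi genotype
  survey and the 16-location deltamethrin bottle-bioassay outcomes.

The synthetic reference sequence is explicitly non-biological: a deterministic
construction that embeds every guide anchor and primer footprint at a geometry
chosen so the susceptible- and resistant-specific PASA products measure
exactly 200 and 280 bp and the K1/K2 sequencing product exactly 448 bp.  The
allele-specific primers' 3' ends sit on the codon-1014 variable base, which
fixes the control (kdr1+kdr4) product at 448 bp as well (the nominal 480-bp
control class absorbs it within gel tolerance); see docs/methods.md.  The
L1014H test is modeled at its own locus so the four assays stay independent.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import pasa as pasa_mod
from .bioassay import TIME_GRID, AssayRun, MortalitySeries
from .genotype_caller import locate_anchor
from .popgen import GenotypeCounts
from .reference_model import (
    GeneModel,
    Genotype,
    load_gene_model,
    packaged_config_path,
    reverse_complement,
)

#: internal seed for the packaged reference construction (not user-tunable:
#: the reference is a fixed artifact, like a packaged FASTA would be)
_REFERENCE_SEED = 20230719


class SyntheticConfigError(ValueError):
    """Invalid simulation parameters."""


# ---------------------------------------------------------------------------
# Packaged worked-example tables (published survey values, used by fixtures,
# the --reproduce-paper comparison mode and the acceptance checks)
# ---------------------------------------------------------------------------

#: (location, n_RR, n_SS, n_RS, printed % column, printed chi2, printed P)
SURVEY_TABLE = (
    ("Mina Zayed",         1,  6,  9, 34.4, 0.9741, 0.3236),
    ("Hadbat Al Zafranah", 0,  0,  6, 18.8, 6.0,    0.0143),
    ("Al Danah",           0,  6, 13, 40.6, 5.1376, 0.0234),
    ("Al Muzoun",          1, 10,  4, 18.8, 0.4166, 0.5186),
    ("Al Mushrif",         1,  6,  3, 15.6, 0.4,    0.527),
    ("Al Bateen",          0,  9,  6, 18.8, 0.9375, 0.3329),
    ("Al Rawdah",          4,  6,  7, 46.9, 0.4623, 0.4965),
    ("Shahama City",       0, 15,  3,  9.4, 0.1487, 0.6997),
    ("Al Samha",           0, 13,  5, 15.6, 0.4682, 0.4937),
    ("Al Bahiya",          1,  3,  4, 18.8, 0.0355, 0.8504),
    ("Baniyas",            1,  6,  1,  9.4, 2.7823, 0.0953),
    ("Mirfa",              1,  9,  4, 18.8, 0.3213, 0.5707),
    ("Madinat Zayed",      2,  9,  7, 34.4, 0.1259, 0.7227),
    ("Al Hayer",           1,  6,  2, 12.5, 1.1479, 0.2839),
    ("Al Khazna",          0, 13,  4, 12.5, 0.3022, 0.5824),
    ("Hili",               1, 15,  4, 15.6, 0.9304, 0.3347),
    ("Remah",              0,  8,  0,  0.0, 0.0,    None),
    ("Central district",   0, 11,  5, 15.6, 0.5486, 0.4588),
    ("Al Shuwaymah",       0, 12, 15, 46.9, 3.994,  0.0456),
)

#: (location, test date 2023, published status, published time to 100% kill)
BIOASSAY_TABLE = (
    ("Al Rawadah",             "10 March", "susceptible", 60),
    ("Al Mushrif",             "15 March", "susceptible", 60),
    ("Al Bateen",              "1 April",  "susceptible", 60),
    ("Al Wathba",              "1 March",  "susceptible", 60),
    ("Al Falah",               "3 March",  "susceptible", 60),
    ("Yas Island",             "6 March",  "susceptible", 60),
    ("Mussafah Shabiya",       "8 March",  "susceptible", 60),
    ("Al Adlah",               "10 March", "susceptible", 60),
    ("Madinat Zayed",          "16 March", "susceptible", 60),
    ("Bida Bint Saud",         "17 April", "susceptible", 60),
    ("Al Shwaib",              "28 April", "resistant",   90),
    ("Al Saa",                 "27 March", "susceptible", 60),
    ("Bu Kirayyah",            "1 March",  "susceptible", 60),
    ("Malaqit",                "14 March", "susceptible", 60),
    ("Al Rawdah Al Sharqiyah", "11 April", "susceptible", 60),
    ("Al Aflaj",               "14 April", "resistant",   90),
)

DIAGNOSTIC_DOSE = 4.5   # ug/ml deltamethrin
DIAGNOSTIC_TIME = 60    # minutes


def survey_genotype_counts() -> list:
    """The 19-location genotype survey as GenotypeCounts."""
    return [
        GenotypeCounts(location=loc, n_RR=rr, n_RS=rs, n_SS=ss)
        for loc, rr, ss, rs, *_ in SURVEY_TABLE
    ]


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceLayout:
    """The packaged synthetic VSSC reference (coding strand, cDNA) plus intron."""

    cdna: str
    intron_sequence: str
    intron_position: int
    codon_starts: Mapping  # site name -> 0-based codon start on cdna

    @property
    def gdna(self) -> str:
        return (
            self.cdna[: self.intron_position]
            + self.intron_sequence
            + self.cdna[self.intron_position :]
        )


# fixed coordinates of the engineered features on the cDNA (see docs/methods.md)
_COORDS = {
    "4Mut_kdr_F": 20,      # forward primer footprint start
    "M918T_guide": 47,     # guide start; codon at 67
    "T929I_guide": 80,     # codon at 100 (33 bp downstream of codon 918)
    "kdr1": 177,           # forward; chosen so kdr1 -> kdr3 product = 200 bp
    "K1": 200,             # forward; chosen so K1 -> K2 product = 448 bp
    "L1014F_context": 342, # ACG + GTCGTGATCGGCAAT, codon 1014 at 360
    "kdr3_rc_tail": 363,   # GTGGTAAGTTGACG completes revcomp(kdr3) from 360
    "L1014H_guide": 400,   # separate locus; codon at 419
    "kdr4_rc": 603,        # reverse footprint; end 625 -> kdr2 product = 280 bp
    "K2_rc": 627,          # reverse footprint; end 648
    "4Mut_kdr_R_rc": 660,  # reverse footprint
}
_CDNA_LENGTH = 700
_INTRON_POSITION = 140  # inside the spacer between the T929 block and kdr1

CODON_STARTS = {"M918T": 67, "T929I": 100, "L1014F": 360, "L1014H": 419}


def _wild_cdna(filler: str) -> str:
    """Assemble the wild-type cDNA from fixed feature blocks and random filler."""
    fill = iter(filler)

    def rnd(n: int) -> str:
        return "".join(next(fill) for _ in range(n))

    parts = [
        rnd(20),                                   # 0    5' pad
        "TCCGGAATTGGAGAAGGTGC",                    # 20   4Mut_kdr_F (forward)
        rnd(7),                                    # 40
        "AATTTACTCATTTCGATTAC",                    # 47   M918T guide
        "ATG",                                     # 67   codon 918 (wild M)
        rnd(10),                                   # 70   codons 919-928 filler
        "GGTGCATTGGGTAATCTGAT",                    # 80   T929I guide
        "ACA",                                     # 100  codon 929 (wild T)
        rnd(74),                                   # 103  spacer (intron splits it in gDNA)
        "AAGGATCGCTTCAAGG",                        # 177  kdr1 (forward)
        rnd(7),                                    # 193
        "TCGCTTCAAGGACCATGAAT",                    # 200  K1 (forward)
        rnd(122),                                  # 220
        "ACG" + "GTCGTGATCGGCAAT",                 # 342  shared 1014 context
        "CTT",                                     # 360  codon 1014 (wild L)
        "GTGGTAAGTTGACG",                          # 363  completes revcomp(kdr3)
        rnd(23),                                   # 377
        "CGGTCGTGATCGGCAATCA",                     # 400  L1014H guide (own locus)
        "CTT",                                     # 419  L1014H test codon
        rnd(181),                                  # 422
        reverse_complement("TTCACCCAGTTCTTAAAACGAG"),  # 603  kdr4 footprint
        rnd(2),                                    # 625
        reverse_complement("TTACGTTTCACCCAGTTCTTA"),   # 627  K2 footprint
        rnd(12),                                   # 648
        reverse_complement("TCAAGCCATCGCCCATGATT"),    # 660  4Mut_kdr_R footprint
        rnd(20),                                   # 680  3' pad
    ]
    seq = "".join(parts)
    assert len(seq) == _CDNA_LENGTH
    return seq


def _bare_model() -> GeneModel:
    return load_gene_model(packaged_config_path())


def _layout_is_sound(layout: "ReferenceLayout", model: GeneModel) -> bool:
    """Reject fillers that create spurious anchors or primer sites."""
    from .pasa import find_binding_sites

    all_rr = {s.name: Genotype.RR for s in model.sites}
    all_rs = {s.name: Genotype.RS for s in model.sites}
    wild = {s.name: Genotype.SS for s in model.sites}

    sequences = []
    for genotypes in (wild, all_rs, all_rr):
        cdna = _substitute(layout.cdna, model, layout.codon_starts, genotypes)
        gdna = layout.intron_sequence.join(
            (cdna[: layout.intron_position], cdna[layout.intron_position :])
        )
        sequences.append(cdna)
        sequences.append(gdna)

    # every guide must anchor uniquely at its designed spot on every rendering
    for seq in sequences:
        intronic = len(seq) > _CDNA_LENGTH
        for site in model.sites:
            try:
                match = locate_anchor(seq, site, max_mismatches=1)
            except ValueError:
                return False
            if match is None or match.strand != "forward":
                return False
            expected = layout.codon_starts[site.name] - (
                len(site.guide_sequence) + site.codon_offset
            )
            if intronic and expected >= layout.intron_position:
                expected += len(layout.intron_sequence)
            if match.position != expected:
                return False

    # primer site counts: one designed site each, kdr2/kdr3 allele-specific
    primers = dict(model.pasa.primers)
    wild_hap = sequences[0]
    res_hap = _substitute(
        layout.cdna, model, layout.codon_starts, {"L1014F": Genotype.RR}
    )
    expected_counts = {
        # (primer, haplotype) -> count
        ("kdr1", "wild"): 1, ("kdr1", "res"): 1,
        ("kdr2", "wild"): 0, ("kdr2", "res"): 1,
        ("kdr3", "wild"): 1, ("kdr3", "res"): 0,
        ("kdr4", "wild"): 1, ("kdr4", "res"): 1,
    }
    for (pname, hap_name), want in expected_counts.items():
        hap = wild_hap if hap_name == "wild" else res_hap
        if len(find_binding_sites(hap, primers[pname])) != want:
            return False
    return True


def _substitute(
    cdna: str,
    model: GeneModel,
    codon_starts: Mapping,
    genotypes: Mapping,
) -> str:
    """Write each site's codon for the given genotypes into the wild cDNA."""
    seq = list(cdna)
    for name, genotype in genotypes.items():
        genotype = Genotype(genotype)
        site = model.site(name)
        start = codon_starts[name]
        if genotype is Genotype.SS:
            codon = site.wild_codon
        elif genotype is Genotype.RR:
            codon = site.mutant_codon
        elif genotype is Genotype.RS:
            codon = (
                site.wild_codon[: site.variable_position - 1]
                + site.het_code
                + site.wild_codon[site.variable_position :]
            )
        else:
            raise SyntheticConfigError(f"cannot render genotype {genotype} at {name}")
        seq[start : start + 3] = codon
    return "".join(seq)


@functools.lru_cache(maxsize=4)
def reference_layout(intron_length: int = 1700) -> ReferenceLayout:
    """Build (deterministically) the packaged synthetic reference.

    Random filler comes from a fixed internal seed; candidate fillers are
    rejected until every guide anchors uniquely and every primer binds exactly
    at its designed footprint on wild, heterozygous and mutant renderings.
    """
    if intron_length <= 0:
        raise SyntheticConfigError("intron_length must be positive")
    model = _bare_model()
    rng = np.random.default_rng(_REFERENCE_SEED)
    bases = np.array(list("ACGT"))
    for _attempt in range(200):
        filler = "".join(rng.choice(bases, size=_CDNA_LENGTH))
        intron = "GT" + "".join(rng.choice(bases, size=intron_length - 4)) + "AG"
        layout = ReferenceLayout(
            cdna=_wild_cdna(filler),
            intron_sequence=intron,
            intron_position=_INTRON_POSITION,
            codon_starts=dict(CODON_STARTS),
        )
        if _layout_is_sound(layout, model):
            return layout
    raise RuntimeError("could not construct a sound synthetic reference")


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KillCurve:
    """Logistic-in-time cumulative kill probability for one resistance status."""

    midpoint: float            # minutes to 50% knockdown
    slope: float               # logistic scale, minutes
    full_kill_time: Optional[int]  # grid time by which every insect is dead


#: study-condition kill curves: susceptible populations reach complete kill at
#: the 60-min diagnostic time; resistant populations only at 90 min
KILL_CURVES = {
    "susceptible": KillCurve(midpoint=30.0, slope=8.0, full_kill_time=60),
    "resistant": KillCurve(midpoint=65.0, slope=8.0, full_kill_time=90),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    Defaults mirror the packaged survey's headline site (N = 16 flies, kdr
    allele frequency 11/32) and the published bottle layout (4 x 25 flies plus
    an acetone control).
    """

    seed: int = 0
    n_individuals: int = 16
    kdr_allele_frequency: float = 0.34375
    inbreeding_F: float = 0.0
    location: str = "synthetic"
    focal_site: str = "L1014F"
    sites_genotype_spec: Optional[Mapping] = None
    intron_length: int = 1700
    n_bottles: int = 4
    insects_per_bottle: int = 25
    binomial_sampling: bool = False  # False = deterministic expected curve
    kill_curves: Mapping = field(default_factory=lambda: dict(KILL_CURVES))

    def __post_init__(self) -> None:
        if not 0.0 <= self.kdr_allele_frequency <= 1.0:
            raise SyntheticConfigError(
                f"kdr_allele_frequency must be in [0, 1], got {self.kdr_allele_frequency}"
            )
        if not -1.0 <= self.inbreeding_F <= 1.0:
            raise SyntheticConfigError(
                f"inbreeding_F must be in [-1, 1], got {self.inbreeding_F}"
            )
        if self.n_individuals < 1:
            raise SyntheticConfigError("n_individuals must be >= 1")


def genotype_probabilities(p: float, F: float) -> tuple:
    """(P(RR), P(RS), P(SS)) under allele frequency p and inbreeding F."""
    q = 1.0 - p
    probs = (p * p + F * p * q, 2 * p * q * (1 - F), q * q + F * p * q)
    if min(probs) < -1e-12:
        raise SyntheticConfigError(
            f"genotype probabilities negative for p={p}, F={F}: {probs}"
        )
    total = sum(probs)
    return tuple(max(x, 0.0) / total for x in probs)


@dataclass
class TruthTable:
    """Per-individual truth genotypes; recoverable exactly from rendered FASTA."""

    table: pd.DataFrame          # columns: individual_id + one per site
    focal_site: str
    realized_allele_frequency: float

    def genotype(self, individual_id: str, site: str) -> Genotype:
        row = self.table.loc[self.table["individual_id"] == individual_id]
        return Genotype(row.iloc[0][site])


def simulate_genotype_counts(config: SimulationConfig, model: Optional[GeneModel] = None):
    """Draw N diploid genotypes at the focal site; returns (counts, truth).

    P(RR) = p^2 + Fpq, P(RS) = 2pq(1-F), P(SS) = q^2 + Fpq.  Non-focal sites
    default to SS unless overridden in ``sites_genotype_spec`` (a mapping of
    site name to a Genotype applied to all individuals, or to a per-individual
    sequence of genotypes).
    """
    model = model or _default_model()
    probs = genotype_probabilities(config.kdr_allele_frequency, config.inbreeding_F)
    rng = np.random.default_rng(config.seed)
    draws = rng.choice(3, size=config.n_individuals, p=probs)
    focal = [(Genotype.RR, Genotype.RS, Genotype.SS)[d] for d in draws]

    spec = dict(config.sites_genotype_spec or {})
    rows = []
    for i, g in enumerate(focal):
        row = {"individual_id": f"{config.location}_{i + 1:03d}"}
        for site in model.sites:
            if site.name == config.focal_site:
                row[site.name] = g.value
            elif site.name in spec:
                v = spec[site.name]
                if isinstance(v, (list, tuple)):
                    row[site.name] = Genotype(v[i]).value
                else:
                    row[site.name] = Genotype(v).value
            else:
                row[site.name] = Genotype.SS.value
        rows.append(row)
    table = pd.DataFrame(rows)
    counts = GenotypeCounts(
        location=config.location,
        n_RR=sum(1 for g in focal if g is Genotype.RR),
        n_RS=sum(1 for g in focal if g is Genotype.RS),
        n_SS=sum(1 for g in focal if g is Genotype.SS),
    )
    kdr = 2 * counts.n_RR + counts.n_RS
    truth = TruthTable(
        table=table,
        focal_site=config.focal_site,
        realized_allele_frequency=kdr / (2 * counts.N),
    )
    return counts, truth


@functools.lru_cache(maxsize=1)
def _default_model() -> GeneModel:
    from .reference_model import default_gene_model

    return default_gene_model(with_reference=True)


# ---------------------------------------------------------------------------
# Sequence rendering
# ---------------------------------------------------------------------------

def render_consensus(
    genotypes: Mapping,
    model: Optional[GeneModel] = None,
    form: str = "cDNA",
    intron_length: int = 1700,
) -> str:
    """One consensus sequence for one individual (het positions as IUPAC codes)."""
    model = model or _default_model()
    layout = reference_layout(intron_length)
    if model.reference_sequence != layout.cdna:
        raise SyntheticConfigError(
            "render_consensus requires the packaged synthetic reference model"
        )
    cdna = _substitute(layout.cdna, model, layout.codon_starts, genotypes)
    if form == "cDNA":
        return cdna
    if form == "gDNA":
        pos = layout.intron_position
        return cdna[:pos] + layout.intron_sequence + cdna[pos:]
    raise SyntheticConfigError(f"form must be 'gDNA' or 'cDNA', got {form!r}")


def render_sequences(
    truth: TruthTable,
    model: Optional[GeneModel] = None,
    form: str = "cDNA",
    fasta_path: Optional[Union[str, Path]] = None,
    intron_length: int = 1700,
) -> list:
    """Render every truth-table individual; returns [(sequence_id, sequence)].

    Optionally writes a FASTA whose record ids equal the individual ids.
    """
    model = model or _default_model()
    site_names = [s.name for s in model.sites]
    out = []
    for _, row in truth.table.iterrows():
        genotypes = {n: Genotype(row[n]) for n in site_names}
        seq = render_consensus(genotypes, model, form=form, intron_length=intron_length)
        out.append((row["individual_id"], seq))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for seq_id, seq in out:
                fh.write(f">{seq_id} form={form}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
    return out


def render_haplotypes(
    genotypes: Mapping,
    model: Optional[GeneModel] = None,
    insect_id: str = "insect",
    rng: Optional[np.random.Generator] = None,
) -> pasa_mod.DiploidTemplate:
    """Two chromosome copies for one individual (PASA template).

    Heterozygous sites place the mutant allele on a random copy (or copy A
    when no RNG is given) — phase is irrelevant to the assay.
    """
    model = model or _default_model()
    hap_genotypes = [{}, {}]
    for name, genotype in genotypes.items():
        genotype = Genotype(genotype)
        if genotype is Genotype.RS:
            which = int(rng.integers(2)) if rng is not None else 0
            hap_genotypes[which][name] = Genotype.RR
            hap_genotypes[1 - which][name] = Genotype.SS
        else:
            hap_genotypes[0][name] = genotype
            hap_genotypes[1][name] = genotype
    haps = [
        render_consensus(hg, model, form="cDNA") for hg in hap_genotypes
    ]
    return pasa_mod.DiploidTemplate(
        insect_id=insect_id, haplotype_a=haps[0], haplotype_b=haps[1]
    )


# ---------------------------------------------------------------------------
# Bioassay simulation
# ---------------------------------------------------------------------------

def _logistic(t: np.ndarray, curve: KillCurve) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - curve.midpoint) / curve.slope))


def _curve_counts(curve: KillCurve, n: int, time_points: Sequence) -> list:
    """Deterministic cumulative death counts following the expected curve."""
    t = np.asarray(time_points, dtype=float)
    frac = _logistic(t, curve)
    dead = np.minimum(np.floor(n * frac).astype(int), n - 1)
    if curve.full_kill_time is not None:
        dead[t >= curve.full_kill_time] = n
    return np.maximum.accumulate(dead).tolist()


def _sampled_counts(
    curve: KillCurve, n: int, time_points: Sequence, rng: np.random.Generator
) -> list:
    """Per-insect logistic death times, capped at the full-kill time."""
    times = rng.logistic(loc=curve.midpoint, scale=curve.slope, size=n)
    if curve.full_kill_time is not None:
        times = np.minimum(times, curve.full_kill_time)
    return [int(np.sum(times <= t)) for t in time_points]


def simulate_bioassay(
    status: str,
    config: SimulationConfig = SimulationConfig(),
    dose: float = DIAGNOSTIC_DOSE,
    location: Optional[str] = None,
    date: str = "",
    curve: Optional[KillCurve] = None,
) -> AssayRun:
    """One bottle-bioassay run (treated replicates + clean control) for a status."""
    if curve is None:
        try:
            curve = config.kill_curves[status]
        except KeyError:
            raise SyntheticConfigError(
                f"status must be one of {sorted(config.kill_curves)}, got {status!r}"
            ) from None
    location = location or f"{status}-site"
    rng = np.random.default_rng(config.seed)
    n = config.insects_per_bottle
    bottles = []
    for b in range(config.n_bottles):
        if config.binomial_sampling:
            dead = _sampled_counts(curve, n, TIME_GRID, rng)
        else:
            dead = _curve_counts(curve, n, TIME_GRID)
        bottles.append(
            MortalitySeries(
                bottle_id=f"{location}-b{b + 1}",
                location=location,
                dose=dose,
                n_insects=n,
                time_points=TIME_GRID,
                cumulative_dead=tuple(dead),
            )
        )
    control = MortalitySeries(
        bottle_id=f"{location}-control",
        location=location,
        dose=0.0,
        n_insects=n,
        time_points=TIME_GRID,
        cumulative_dead=(0,) * len(TIME_GRID),
    )
    return AssayRun(location=location, date=date, treated=tuple(bottles), control=control)


#: dose ladder used to calibrate the diagnostic dose on the susceptible strain;
#: sub-diagnostic doses plateau below complete kill, the diagnostic dose first
#: reaches it at 60 min, and a higher dose reaches it earlier
PANEL_CURVES = {
    1.0: KillCurve(midpoint=100.0, slope=12.0, full_kill_time=None),
    2.0: KillCurve(midpoint=80.0, slope=10.0, full_kill_time=None),
    DIAGNOSTIC_DOSE: KILL_CURVES["susceptible"],
    9.0: KillCurve(midpoint=15.0, slope=5.0, full_kill_time=30),
}


def make_susceptible_panel(config: SimulationConfig = SimulationConfig()) -> list:
    """Susceptible-strain dose ladder whose diagnostic resolves to (4.5, 60)."""
    return [
        simulate_bioassay(
            "susceptible", config, dose=dose,
            location=f"susceptible-strain-{dose}", curve=curve,
        )
        for dose, curve in sorted(PANEL_CURVES.items())
    ]


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

#: six demonstration flies covering all genotype classes across the four sites
DEMO_FLIES = (
    ("fly01", {}),
    ("fly02", {"L1014F": Genotype.RR}),
    ("fly03", {"L1014F": Genotype.RS}),
    ("fly04", {"T929I": Genotype.RS, "L1014F": Genotype.RR}),
    ("fly05", {"M918T": Genotype.RR, "T929I": Genotype.RS}),
    ("fly06", {"L1014H": Genotype.RS}),
)


def demo_truth_table(model: Optional[GeneModel] = None) -> TruthTable:
    model = model or _default_model()
    rows = []
    for fly_id, spec in DEMO_FLIES:
        row = {"individual_id": fly_id}
        for site in model.sites:
            row[site.name] = spec.get(site.name, Genotype.SS).value
        rows.append(row)
    table = pd.DataFrame(rows)
    rr = sum(1 for _, s in DEMO_FLIES if s.get("L1014F") is Genotype.RR)
    rs = sum(1 for _, s in DEMO_FLIES if s.get("L1014F") is Genotype.RS)
    return TruthTable(
        table=table,
        focal_site="L1014F",
        realized_allele_frequency=(2 * rr + rs) / (2 * len(DEMO_FLIES)),
    )


def bioassay_survey_runs(seed: int = 0) -> list:
    """AssayRuns reproducing each published bioassay row's status and kill time."""
    runs = []
    for i, (location, date, status, _time100) in enumerate(BIOASSAY_TABLE):
        config = SimulationConfig(seed=seed + i)
        runs.append(
            simulate_bioassay(status, config, dose=DIAGNOSTIC_DOSE,
                              location=location, date=date)
        )
    return runs


def _runs_to_frame(runs: Sequence) -> pd.DataFrame:
    rows = []
    for run in runs:
        for series in (*run.treated, run.control):
            row = {
                "location": run.location,
                "date": run.date,
                "bottle_id": series.bottle_id,
                "dose_ug_ml": series.dose,
                "n_insects": series.n_insects,
            }
            for t, d in zip(series.time_points, series.cumulative_dead):
                row[f"dead_{t}"] = d
            rows.append(row)
    return pd.DataFrame(rows)


def make_paper_fixtures(
    outdir: Union[str, Path], seed: int = 0, model: Optional[GeneModel] = None
) -> dict:
    """Write the packaged worked-example files; returns {name: path}.

    * ``survey_genotype_counts.csv`` — the 19-location RR/RS/SS tallies;
    * ``bottle_bioassay.csv`` — per-bottle mortality series reproducing each
      published location's resistance status and time to 100% kill;
    * ``demo_flies.fasta`` + ``demo_flies_truth.csv`` — six synthetic flies
      covering all genotype classes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model = model or _default_model()
    paths = {}

    counts_path = outdir / "survey_genotype_counts.csv"
    with open(counts_path, "w") as fh:
        fh.write("# kdrkit worked example: 19-location Abu Dhabi genotype survey\n")
        pd.DataFrame(
            [
                {"location": c.location, "n_RR": c.n_RR, "n_RS": c.n_RS, "n_SS": c.n_SS}
                for c in survey_genotype_counts()
            ]
        ).to_csv(fh, index=False)
    paths["survey_genotype_counts"] = counts_path

    bioassay_path = outdir / "bottle_bioassay.csv"
    with open(bioassay_path, "w") as fh:
        fh.write(
            f"# kdrkit worked example: deltamethrin bottle bioassay (seed={seed})\n"
        )
        _runs_to_frame(bioassay_survey_runs(seed)).to_csv(fh, index=False)
    paths["bottle_bioassay"] = bioassay_path

    truth = demo_truth_table(model)
    fasta_path = outdir / "demo_flies.fasta"
    render_sequences(truth, model, form="cDNA", fasta_path=fasta_path)
    paths["demo_flies_fasta"] = fasta_path

    truth_path = outdir / "demo_flies_truth.csv"
    with open(truth_path, "w") as fh:
        fh.write(f"# kdrkit demonstration truth table (seed={seed})\n")
        truth.table.to_csv(fh, index=False)
    paths["demo_flies_truth"] = truth_path
    return paths
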