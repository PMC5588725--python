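"""Synthetic labeled cohorts with the statistical structure the model assumes.

The generator emulates the data model behind the classifier: per-patient
bags of CDR3 amino-acid sequences of varying length, where a minority of
case-patient CDR3s carry a planted biochemical motif and everything else is
background.  Case/control separation therefore rests on rare high-scoring
snippets, exactly the multiple-instance assumption of max pooling.

Everything is deterministic under ``SimConfig.seed``; the emitted
:class:`SimTruth` records which CDR3s carry the motif and at which offset,
so recovery can be checked by string search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .atchley import AMINO_ACIDS, ATCHLEY_TABLE
from .featurization import FeatureEncoding, Snippet, encode_snippet
from .genetic_code import CODON_TO_AA, SYNONYMOUS_CODONS
from .preprocessing import Cohort, Repertoire

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_cohort",
    "plant_motif",
    "nucleotide_backfill",
    "translate",
    "motif_variants",
    "preset_config",
    "PRESETS",
]

#: Residues enriched in the skewed CDR3-like background.
_CDR3_ENRICHED = "GSYAR"


@dataclass
class SimConfig:
    """Generator settings.

    CDR3 lengths are drawn from a shifted-binomial distribution over
    ``length_min..length_max`` peaking near 14 residues, echoing human heavy
    chain CDR3 length profiles.  ``motif_prevalence`` is the fraction of case
    patients carrying the motif; each carrier receives
    ``plants_per_carrier`` motif-bearing CDR3s (uniform over the inclusive
    range).  ``motif_mode='biochemical'`` plants random single-residue
    variants of the motif that stay within ``atchley_radius`` (Euclidean, in
    factor space) of the original residue, to exercise non-identical-sequence
    generalization.  ``contamination_rate`` copies that fraction of CDR3s
    into a second patient to exercise shared-sequence removal.
    """

    n_cases: int = 12
    n_controls: int = 12
    cdr3s_per_patient: tuple[int, int] = (100, 100)
    length_min: int = 6
    length_max: int = 24
    motif: str = "QKRAAD"
    motif_prevalence: float = 1.0
    plants_per_carrier: tuple[int, int] = (1, 5)
    motif_mode: str = "exact"
    atchley_radius: float = 1.2
    background: str = "uniform"
    contamination_rate: float = 0.0
    with_nucleotides: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.motif_prevalence <= 1.0:
            raise ValueError("motif_prevalence must lie in [0, 1]")
        if not 0.0 <= self.contamination_rate <= 1.0:
            raise ValueError("contamination_rate must lie in [0, 1]")
        if self.motif_mode not in ("exact", "biochemical"):
            raise ValueError("motif_mode must be 'exact' or 'biochemical'")
        if self.background not in ("uniform", "cdr3like"):
            raise ValueError("background must be 'uniform' or 'cdr3like'")
        if len(self.motif) > self.length_min:
            # every CDR3 must be able to host the motif for prevalence logic
            if len(self.motif) > self.length_max:
                raise ValueError("motif longer than the maximum CDR3 length")
        if not set(self.motif) <= set(AMINO_ACIDS):
            raise ValueError("motif must use standard residues")


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    motif: str
    #: patient_id -> list of (cdr3_index, offset, planted text)
    plants: dict[str, list[tuple[int, int, str]]] = field(default_factory=dict)
    #: direction in feature space the plants realize (Atchley encoding of motif)
    direction: np.ndarray | None = None
    contaminated: list[tuple[str, str, int]] = field(default_factory=list)


def _length_pmf(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    span = config.length_max - config.length_min
    p = (14 - config.length_min) / span if span > 0 else 0.5
    p = min(max(p, 0.05), 0.95)
    ks = np.arange(span + 1)
    pmf = stats.binom.pmf(ks, span, p)
    return config.length_min + ks, pmf / pmf.sum()


def _draw_background(rng: np.random.Generator, length: int, background: str) -> str:
    if background == "uniform":
        idx = rng.integers(0, len(AMINO_ACIDS), size=length)
        return "".join(AMINO_ACIDS[i] for i in idx)
    # CDR3-like: CAR...W flanks, enriched interior
    interior_len = max(length - 4, 0)
    weights = np.ones(len(AMINO_ACIDS))
    for aa in _CDR3_ENRICHED:
        weights[AMINO_ACIDS.index(aa)] = 4.0
    weights /= weights.sum()
    idx = rng.choice(len(AMINO_ACIDS), size=interior_len, p=weights)
    interior = "".join(AMINO_ACIDS[i] for i in idx)
    return ("CAR" + interior + "W")[:length]


def plant_motif(cdr3: str, motif: str, offset: int) -> str:
    """Substitute ``motif`` into ``cdr3`` at ``offset``; length preserved."""
    if offset < 0 or offset + len(motif) > len(cdr3):
        raise ValueError(
            f"cannot plant length-{len(motif)} motif at offset {offset} "
            f"of a length-{len(cdr3)} CDR3"
        )
    return cdr3[:offset] + motif + cdr3[offset + len(motif) :]


def motif_variants(motif: str, radius: float) -> list[str]:
    """All single-residue substitutions within ``radius`` in Atchley space.

    Distance is the Euclidean norm between the substituted residue's factor
    vector and the original's.  The motif itself is always included.
    """
    table = {aa: np.array(v) for aa, v in ATCHLEY_TABLE.items()}
    variants = [motif]
    for pos, orig in enumerate(motif):
        for aa in AMINO_ACIDS:
            if aa == orig:
                continue
            if np.linalg.norm(table[aa] - table[orig]) <= radius:
                variants.append(motif[:pos] + aa + motif[pos + 1 :])
    return variants


def nucleotide_backfill(cdr3_aa: str, rng: np.random.Generator) -> str:
    """One uniformly random codon spelling per residue; translates back exactly."""
    codons = []
    for aa in cdr3_aa:
        options = SYNONYMOUS_CODONS[aa]
        codons.append(options[int(rng.integers(0, len(options)))])
    return "".join(codons)


def translate(cdr3_nt: str) -> str:
    """Standard-code translation (round-trip check for the backfill)."""
    if len(cdr3_nt) % 3 != 0:
        raise ValueError("nucleotide length not a multiple of 3")
    return "".join(CODON_TO_AA[cdr3_nt[i : i + 3]] for i in range(0, len(cdr3_nt), 3))


def simulate_cohort(config: SimConfig) -> tuple[Cohort, SimTruth]:
    """Generate a labeled cohort plus its ground truth.

    Controls contain zero motif plants; each motif-carrying case CDR3 embeds
    the motif (or a biochemical variant) at a uniform-random feasible
    offset; background residues are i.i.d. from the background model.
    """
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(int(config.seed))))
    lengths, pmf = _length_pmf(config)
    variants = (
        motif_variants(config.motif, config.atchley_radius)
        if config.motif_mode == "biochemical"
        else [config.motif]
    )

    truth = SimTruth(motif=config.motif, plants={})
    enc = FeatureEncoding("atchley", len(config.motif))
    truth.direction = encode_snippet(Snippet(config.motif, -1, 0, "truth"), enc)

    n_carriers = int(round(config.motif_prevalence * config.n_cases))
    carrier_ids = set(rng.choice(config.n_cases, size=n_carriers, replace=False).tolist())

    repertoires = []
    width = len(str(config.n_cases + config.n_controls))
    for label, count, prefix in ((1, config.n_cases, "case"), (0, config.n_controls, "ctrl")):
        for i in range(count):
            pid = f"{prefix}{i + 1:0{width}d}"
            lo, hi = config.cdr3s_per_patient
            n_cdr3 = int(rng.integers(lo, hi + 1))
            ls = rng.choice(lengths, size=n_cdr3, p=pmf)
            cdr3s = [_draw_background(rng, int(L), config.background) for L in ls]
            plants = []
            if label == 1 and i in carrier_ids:
                k = len(config.motif)
                feasible = [j for j, s in enumerate(cdr3s) if len(s) >= k]
                n_plants = int(
                    rng.integers(config.plants_per_carrier[0], config.plants_per_carrier[1] + 1)
                )
                n_plants = min(n_plants, len(feasible))
                chosen = rng.choice(feasible, size=n_plants, replace=False)
                for j in sorted(int(c) for c in chosen):
                    off = int(rng.integers(0, len(cdr3s[j]) - k + 1))
                    text = variants[int(rng.integers(0, len(variants)))]
                    cdr3s[j] = plant_motif(cdr3s[j], text, off)
                    plants.append((j, off, text))
            truth.plants[pid] = plants
            repertoires.append(Repertoire(patient_id=pid, label=label, cdr3_aa=cdr3s))

    # cross-patient contamination: copy sequences between patients
    total = sum(len(r) for r in repertoires)
    n_copy = int(round(config.contamination_rate * total))
    planted_idx = {
        rep.patient_id: {j for j, _, _ in truth.plants.get(rep.patient_id, [])}
        for rep in repertoires
    }
    for _ in range(n_copy):
        di, ri = rng.choice(len(repertoires), size=2, replace=False)
        donor, recip = repertoires[di], repertoires[ri]
        src = int(rng.integers(0, len(donor)))
        candidates = [
            j for j in range(len(recip)) if j not in planted_idx[recip.patient_id]
        ]
        if not candidates:
            continue
        dst = candidates[int(rng.integers(0, len(candidates)))]
        recip.cdr3_aa[dst] = donor.cdr3_aa[src]
        truth.contaminated.append((donor.patient_id, recip.patient_id, dst))

    if config.with_nucleotides:
        for rep in repertoires:
            rep.cdr3_nt = [nucleotide_backfill(aa, rng) for aa in rep.cdr3_aa]

    cohort = Cohort(
        repertoires,
        provenance={
            "generator": "maxsnippet.simulate",
            "seed": config.seed,
            "motif": config.motif,
            "motif_prevalence": config.motif_prevalence,
            "background": config.background,
        },
    )
    return cohort, truth


#: Named study conditions.  ``separable``: every case carries two exact
#: plants of the motif among 100 CDR3s — linearly separable in snippet
#: space.  ``null``: no plants at all, for chance-level controls (kept small
#: because its use is Monte-Carlo replication).  ``biochemical``: plants are
#: Atchley-neighborhood variants rather than one literal k-mer.
PRESETS: dict[str, dict] = {
    "separable": dict(
        n_cases=12, n_controls=12, cdr3s_per_patient=(100, 100),
        motif_prevalence=1.0, plants_per_carrier=(2, 2), motif_mode="exact",
    ),
    "null": dict(
        n_cases=8, n_controls=8, cdr3s_per_patient=(20, 20),
        motif_prevalence=0.0,
    ),
    "biochemical": dict(
        n_cases=12, n_controls=12, cdr3s_per_patient=(100, 100),
        motif_prevalence=1.0, plants_per_carrier=(2, 2),
        motif_mode="biochemical", atchley_radius=1.2,
    ),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """A :class:`SimConfig` for one of the named presets."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)
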