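"""Meiosis in translocation heterozygotes: multivalents, segregation,
sterility and F2 ratios.

Model
-----
In a heterozygote, the four chromosomes of one reciprocal translocation
(two normal, two recombinant) synapse as a quadrivalent at diakinesis.
Alternate (zig-zag) disjunction sends the two normal chromosomes to one
pole and the two recombinant ones to the other, giving balanced gametes of
two classes: all-normal (N) and all-translocated (T).  Adjacent disjunction
gives duplication/deficiency gametes that abort.  With alternate frequency
``a`` per multivalent, a gamete is balanced with probability ``a`` and its
balanced class is N or T with probability ``a/2`` each; independent events
multiply.

Under the balanced-only viability rule, surviving gametes carry N or T with
probability 1/2 per event, so selfing a heterozygote gives the Mendelian
NN:NT:TT = 1:2:1 per event, a fully homozygous (fertile, normal-pollen)
fraction of (1/2)^k for k independent heterozygous events — hence the
classic normal : semi-sterile ratios of 1:1 (k=1) and 1:3 (k=2) — and a
pollen sterility of 1 - prod(a_i).

Chained complex translocations (three donors, multivalent of six) have no
closed-form segregation; an explicit segregation table must be supplied.
``uniform_chain_table`` enumerates 3:3 disjunctions uniformly (2 of the 20
are balanced); predictions made with it are flagged model-dependent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binomtest


class MeiosisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# karyotype configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventCarrier:
    """One translocation event carried by an individual.

    ``zygosity``: "heterozygous" (one normal + one translocated chromosome
    set) or "homozygous" (both sets translocated); ``n_donors`` is the
    number of wild-type chromosomes participating (2 for reciprocal).
    """

    event_id: str
    kind: str = "reciprocal"  # "reciprocal" | "complex_chain"
    n_donors: int = 2
    zygosity: str = "heterozygous"

    def __post_init__(self) -> None:
        if self.kind not in ("reciprocal", "complex_chain"):
            raise MeiosisError(f"unknown event kind {self.kind!r}")
        if self.kind == "reciprocal" and self.n_donors != 2:
            raise MeiosisError("reciprocal events involve exactly 2 donors")
        if self.kind == "complex_chain" and self.n_donors < 3:
            raise MeiosisError("complex_chain events involve >= 3 donors")
        if self.zygosity not in ("heterozygous", "homozygous"):
            raise MeiosisError(f"unknown zygosity {self.zygosity!r}")


@dataclass
class KaryotypeConfig:
    n_chromosome_pairs: int = 11
    events: list[EventCarrier] = field(default_factory=list)

    def __post_init__(self) -> None:
        used = 0
        for e in self.events:
            used += e.n_donors
        if used > self.n_chromosome_pairs:
            raise MeiosisError(
                "events claim more chromosome pairs than the karyotype has; "
                "shared donors must be declared as one chained complex event"
            )

    @property
    def het_events(self) -> list[EventCarrier]:
        return [e for e in self.events if e.zygosity == "heterozygous"]


@dataclass
class SegregationParams:
    """``alternate_freq``: probability of alternate (balanced) segregation
    per multivalent — a float applied to all events or a per-event map.
    ``viability``: "balanced_only" or a custom map allele-tuple -> weight.
    ``complex_table``: segregation table required for chained events, as
    returned by :func:`uniform_chain_table`."""

    alternate_freq: float | dict[str, float] = 0.5
    viability: str | dict[tuple[str, ...], float] = "balanced_only"
    complex_table: dict[str, float] | None = None
    ovule_alternate_freq: float | dict[str, float] | None = None

    def a_for(self, event_id: str) -> float:
        a = (self.alternate_freq.get(event_id, 0.5)
             if isinstance(self.alternate_freq, dict) else self.alternate_freq)
        if not 0.0 <= a <= 1.0:
            raise MeiosisError(f"alternate frequency {a} outside [0, 1]")
        return a


def uniform_chain_table(n_donors: int) -> dict[str, float]:
    """Gamete class table for a chained multivalent of 2*n_donors
    chromosomes under uniform random n:n disjunction.

    Of the C(2n, n) equally likely splits only the all-normal and
    all-translocated complements are balanced.
    """
    from math import comb

    total = comb(2 * n_donors, n_donors)
    p = 1.0 / total
    return {"N": p, "T": p, "U": 1.0 - 2.0 * p}


# ---------------------------------------------------------------------------
# diakinesis configurations
# ---------------------------------------------------------------------------


def predict_diakinesis_configuration(config: KaryotypeConfig) -> dict[str, int]:
    """Counts of bivalents and multivalents expected at diakinesis.

    Each heterozygous reciprocal event ties its 2 chromosome pairs into one
    quadrivalent; a heterozygous chained event over c donors forms one
    multivalent of 2c chromosomes.  Homozygous events pair as normal
    bivalents.
    """
    bivalents = config.n_chromosome_pairs
    quadrivalents = 0
    multivalents: dict[int, int] = {}
    for e in config.het_events:
        bivalents -= e.n_donors
        if e.n_donors == 2:
            quadrivalents += 1
        else:
            size = 2 * e.n_donors
            multivalents[size] = multivalents.get(size, 0) + 1
    out = {"bivalents": bivalents, "quadrivalents": quadrivalents}
    for size in sorted(multivalents):
        out[f"multivalent_{size}"] = multivalents[size]
    return out


# ---------------------------------------------------------------------------
# gamete distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GameteClass:
    alleles: tuple[str, ...]  # per heterozygous event: "N", "T" or "U"
    probability: float
    balanced: bool


@dataclass
class GameteDistribution:
    event_ids: tuple[str, ...]
    classes: list[GameteClass]

    @property
    def balanced_fraction(self) -> float:
        return sum(c.probability for c in self.classes if c.balanced)

    def validate(self) -> None:
        total = sum(c.probability for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise MeiosisError(f"gamete probabilities sum to {total}, not 1")


def enumerate_gametes(
    config: KaryotypeConfig, params: SegregationParams
) -> GameteDistribution:
    """Joint gamete-class distribution over the heterozygous events.

    Per reciprocal event the classes are N and T (each a/2) and unbalanced
    (1-a); chained events require ``params.complex_table``.  Independent
    events combine multiplicatively; a gamete is balanced iff it is
    balanced at every event.
    """
    per_event: list[list[tuple[str, float]]] = []
    ids = []
    for e in config.het_events:
        ids.append(e.event_id)
        if e.kind == "reciprocal":
            a = params.a_for(e.event_id)
            per_event.append([("N", a / 2), ("T", a / 2), ("U", 1 - a)])
        else:
            if params.complex_table is None:
                raise MeiosisError(
                    f"chained event {e.event_id!r} needs an explicit "
                    "segregation table (params.complex_table); see "
                    "uniform_chain_table for a documented default"
                )
            t = params.complex_table
            per_event.append([("N", t["N"]), ("T", t["T"]), ("U", t["U"])])
    classes = []
    for combo in itertools.product(*per_event) if per_event else [()]:
        alleles = tuple(c[0] for c in combo)
        prob = float(np.prod([c[1] for c in combo])) if combo else 1.0
        if prob <= 0.0:
            continue
        classes.append(GameteClass(alleles, prob, balanced="U" not in alleles))
    dist = GameteDistribution(tuple(ids), classes)
    dist.validate()
    return dist


def _surviving_allele_probs(
    config: KaryotypeConfig, params: SegregationParams
) -> dict[str, dict[str, float]]:
    """Per-event allele probabilities among viable gametes."""
    dist = enumerate_gametes(config, params)
    if params.viability == "balanced_only":
        weights = {c.alleles: (1.0 if c.balanced else 0.0) for c in dist.classes}
    elif isinstance(params.viability, dict):
        weights = {c.alleles: params.viability.get(c.alleles, 0.0) for c in dist.classes}
    else:
        raise MeiosisError(f"unknown viability rule {params.viability!r}")
    total = sum(c.probability * weights[c.alleles] for c in dist.classes)
    if total <= 0.0:
        raise MeiosisError("no viable gametes under the supplied viability rule")
    out: dict[str, dict[str, float]] = {}
    for i, ev in enumerate(dist.event_ids):
        probs: dict[str, float] = {}
        for c in dist.classes:
            w = c.probability * weights[c.alleles] / total
            probs[c.alleles[i]] = probs.get(c.alleles[i], 0.0) + w
        out[ev] = probs
    return out


# ---------------------------------------------------------------------------
# expectations and simulation
# ---------------------------------------------------------------------------


def expected_f2_segregation(
    config: KaryotypeConfig, params: SegregationParams | None = None
) -> dict:
    """Expected zygote classes when a heterozygote is selfed.

    With balanced-only gamete viability each heterozygous event segregates
    NN:NT:TT = 1:2:1 among surviving zygotes; a plant is pollen-semi-sterile
    iff heterozygous for at least one event, so the fully fertile (normal)
    fraction is (1/2)^k for k independent heterozygous events.
    """
    params = params or SegregationParams()
    het = config.het_events
    k = len(het)
    for e in het:
        if e.kind != "reciprocal" and params.complex_table is None:
            raise MeiosisError(
                f"chained event {e.event_id!r} needs params.complex_table; "
                "its F2 prediction is model-dependent"
            )
    fertile = 0.5 ** k
    genotype_probs = {}
    for e in het:
        genotype_probs[e.event_id] = {"NN": 0.25, "NT": 0.5, "TT": 0.25}
    return {
        "k": k,
        "per_event_genotype_ratio": (1, 2, 1),
        "genotype_probs": genotype_probs,
        "fully_homozygous_fraction": fertile,
        "normal_to_semisterile": (1, 2 ** k - 1),
        "p_semisterile": 1.0 - fertile,
        "model_dependent": any(e.kind != "reciprocal" for e in het),
    }


def simulate_cross(
    parent1: KaryotypeConfig,
    parent2: KaryotypeConfig,
    params: SegregationParams,
    n_offspring: int,
    seed: int,
) -> pd.DataFrame:
    """Draw offspring genotypes from viable gametes of both parents.

    Columns: individual, one genotype column per event (NN/NT/TT), and
    ``phenotype`` (normal / semi_sterile by the heterozygosity rule).
    Deterministic for a fixed seed.
    """
    if n_offspring < 1:
        raise MeiosisError("n_offspring must be >= 1")
    rng = np.random.default_rng(seed)
    event_ids = sorted(
        {e.event_id for e in parent1.events} | {e.event_id for e in parent2.events}
    )
    allele_probs = []
    for parent in (parent1, parent2):
        probs = _surviving_allele_probs(parent, params)
        zyg = {e.event_id: e.zygosity for e in parent.events}
        per_event = {}
        for ev in event_ids:
            if ev in probs:  # heterozygous: segregating among viable gametes
                per_event[ev] = probs[ev]
            elif zyg.get(ev) == "homozygous":
                per_event[ev] = {"T": 1.0}
            else:
                per_event[ev] = {"N": 1.0}
        allele_probs.append(per_event)

    data: dict[str, list] = {"individual": [f"ind{i + 1}" for i in range(n_offspring)]}
    het_mask = np.zeros(n_offspring, dtype=bool)
    for ev in event_ids:
        alleles = []
        for per_event in allele_probs:
            p = per_event[ev]
            keys = sorted(p)
            alleles.append(rng.choice(keys, size=n_offspring, p=[p[k] for k in keys]))
        genotype = np.array(["".join(sorted((x, y))) for x, y in zip(*alleles)])
        data[ev] = genotype
        het_mask |= genotype == "NT"
    data["phenotype"] = np.where(het_mask, "semi_sterile", "normal")
    return pd.DataFrame(data)


def predict_sterility_and_seed_reduction(
    config: KaryotypeConfig, params: SegregationParams | None = None
) -> tuple[float, float]:
    """(pollen sterility, expected seed-set reduction) of a heterozygote.

    Pollen sterility is the unbalanced-gamete fraction 1 - prod(a_i).  Seed
    reduction applies the same rule to the ovule side (symmetric
    gametophyte model) unless ``params.ovule_alternate_freq`` overrides the
    ovule alternate frequencies.
    """
    params = params or SegregationParams()

    def unbalanced(freqs) -> float:
        prod = 1.0
        for e in config.het_events:
            if e.kind == "reciprocal":
                if isinstance(freqs, dict):
                    a = freqs.get(e.event_id, 0.5)
                else:
                    a = freqs
            else:
                if params.complex_table is None:
                    raise MeiosisError(
                        f"chained event {e.event_id!r} needs params.complex_table")
                a = params.complex_table["N"] + params.complex_table["T"]
            prod *= a
        return 1.0 - prod

    pollen = unbalanced(params.alternate_freq)
    ovule_freqs = (params.ovule_alternate_freq
                   if params.ovule_alternate_freq is not None
                   else params.alternate_freq)
    seed = unbalanced(ovule_freqs)
    return pollen, seed


@dataclass
class AlternateFreqEstimate:
    a_hat: float
    ci: tuple[float, float]
    observed_sterility: float
    k: int
    n_scored: int


def estimate_alternate_frequency(
    observed_sterility: float,
    k: int,
    n_scored: int,
    confidence: float = 0.95,
) -> AlternateFreqEstimate:
    """Invert the sterility model: a_hat = (1 - sterility)^(1/k).

    The confidence interval transforms a Wilson binomial interval on the
    observed sterile fraction (``n_scored`` pollen grains scored).
    """
    if not 0.0 <= observed_sterility <= 1.0:
        raise MeiosisError("observed_sterility must be in [0, 1]")
    if k < 1:
        raise MeiosisError("k must be >= 1")
    if n_scored < 1:
        raise MeiosisError("n_scored must be >= 1")
    if observed_sterility == 1.0:
        warnings.warn("observed sterility of 1 gives a degenerate estimate a=0",
                      stacklevel=2)
    a_hat = (1.0 - observed_sterility) ** (1.0 / k)
    count = int(round(observed_sterility * n_scored))
    ci_s = binomtest(count, n_scored).proportion_ci(
        confidence_level=confidence, method="wilson")
    lo = (1.0 - ci_s.high) ** (1.0 / k)
    hi = (1.0 - ci_s.low) ** (1.0 / k)
    return AlternateFreqEstimate(a_hat, (lo, hi), observed_sterility, k, n_scored)
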