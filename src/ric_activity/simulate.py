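"""Synthetic MS-like RIC / WCE / noCL experiments with known ground truth.

The generative model mirrors the two determinants of a protein's RIC/WCE
ratio: the fraction phi of the protein bound to poly(A)+ RNA in vivo and
its UV-crosslink efficiency kappa.  In log2 intensity space, for protein g
in replicate i of a batch:

    WCE_{g,i}  = log2(A_g)                + b_i + u^WCE_{c(g),i}  + eps_{g,i}
    RIC_{g,i}  = log2(A_g phi_g kap_g C)  + b_i + u^RIC_{c(g),i}  + eps_{g,i}
    noCL_{g,i} = log2(A_g beta C)         + b_i + eps'_{g,i}

where A_g is abundance, C the capture efficiency, beta the non-crosslinked
background capture level, b_i a per-sample offset, u a complex-shared noise
term drawn per fraction and replicate (proteins outside annotated complexes
form size-1 complexes and get independent u), and eps a culture-level
replicate noise shared by the RIC and WCE samples of the same replicate
(the WCE is the input of that pull-down, so abundance fluctuations cancel
in paired RIC-WCE ratios).  noCL captures come from separate non-crosslinked
cultures and draw independent eps'.  Any value below the detection limit L
is left-censored to missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import AnnotationTable, IntensityTable, SampleMeta


@dataclass(frozen=True)
class DistSpec:
    """A distribution on (0, 1] or an interval, sampled by the generator.

    kinds: ``fixed`` (value,), ``uniform`` (low, high),
    ``loguniform`` (low, high), ``beta`` (a, b).
    """

    kind: str
    params: tuple[float, ...]

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.kind == "fixed":
            return np.full(size, float(self.params[0]))
        if self.kind == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size)
        if self.kind == "loguniform":
            lo, hi = self.params
            return np.exp(rng.uniform(math.log(lo), math.log(hi), size))
        if self.kind == "beta":
            a, b = self.params
            return rng.beta(a, b, size)
        raise ValueError(f"unknown distribution kind {self.kind!r}")


@dataclass(frozen=True)
class BoundFractionModel:
    """Two-component mixture for the in vivo RNA-bound fraction phi."""

    fraction_high: float = 0.3
    high: DistSpec = DistSpec("loguniform", (0.25, 1.0))
    low: DistSpec = DistSpec("loguniform", (0.005, 0.05))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the simulated RIC experiment.

    Defaults mirror the two-batch triplicate design (noCL only in the first
    batch) and a label-free MS-like intensity scale with detection limit 18
    (log2).  Noise is additive Gaussian in log2 space.
    """

    n_proteins: int = 2000
    n_complexes: int = 100
    complex_size_mean: float = 4.0
    abundance_log2_mean: float = 25.0
    abundance_log2_sd: float = 3.0
    bound_fraction: BoundFractionModel = field(default_factory=BoundFractionModel)
    crosslink_eff: DistSpec = DistSpec("loguniform", (0.05, 0.3))
    capture_eff: float = 0.5
    nocl_background: float = 0.01
    detection_limit: float = 18.0
    sigma_rep: float = 0.3
    sigma_cplx: float = 0.1
    batch_effect_sd: float = 0.05
    n_replicates: int = 3
    n_batches: int = 2
    nocl_batches: tuple[str, ...] = ("B1",)
    genotype: str = "WT"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.nocl_background < 1.0:
            raise ValueError("nocl_background must be in [0, 1)")
        for name in ("sigma_rep", "sigma_cplx", "batch_effect_sd", "abundance_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.capture_eff <= 0:
            raise ValueError("capture_eff must be positive")


@dataclass(frozen=True)
class MutantSpec:
    """Which proteins/complexes shift in the mutant, by how much (log2 of phi)."""

    delta: float
    protein_ids: tuple[str, ...] = ()
    complex_ids: tuple[str, ...] = ()


TRUTH_COLUMNS = [
    "protein_id",
    "abundance",
    "bound_fraction",
    "crosslink_eff",
    "complex_id",
    "mutant_effect",
    "mutant_effect_realized",
]


def _draw_truth(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_proteins
    ids = [f"P{i:05d}" for i in range(1, n + 1)]
    abundance_log2 = rng.normal(config.abundance_log2_mean, config.abundance_log2_sd, n)

    bf = config.bound_fraction
    is_high = rng.random(n) < bf.fraction_high
    phi = np.where(
        is_high, bf.high.sample(rng, n), bf.low.sample(rng, n)
    )
    phi = np.clip(phi, None, 1.0)
    kappa = np.clip(config.crosslink_eff.sample(rng, n), None, 1.0)

    # complex membership: draw sizes, then assign distinct proteins
    complex_id = np.array([None] * n, dtype=object)
    if config.n_complexes > 0:
        order = rng.permutation(n)
        pos = 0
        for c in range(1, config.n_complexes + 1):
            size = 2 + rng.poisson(max(config.complex_size_mean - 2.0, 0.0))
            members = order[pos : pos + size]
            if len(members) < 2:
                break
            complex_id[members] = f"C{c:04d}"
            pos += size
            if pos >= n:
                break

    return pd.DataFrame(
        {
            "protein_id": ids,
            "abundance": np.exp2(abundance_log2),
            "bound_fraction": phi,
            "crosslink_eff": kappa,
            "complex_id": complex_id,
            "mutant_effect": 0.0,
            "mutant_effect_realized": 0.0,
        }
    ).set_index("protein_id", drop=False)


def _complex_units(truth: pd.DataFrame) -> np.ndarray:
    """Integer complex-unit index per protein; singletons are their own unit."""
    units = np.empty(len(truth), dtype=int)
    mapping: dict[object, int] = {}
    nxt = 0
    for i, (pid, cid) in enumerate(zip(truth["protein_id"], truth["complex_id"])):
        key = cid if cid is not None else ("singleton", pid)
        if key not in mapping:
            mapping[key] = nxt
            nxt += 1
        units[i] = mapping[key]
    return units


def _log2_or_minus_inf(x: float) -> float:
    return math.log2(x) if x > 0 else -math.inf


def _simulate_tables(
    config: GeneratorConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator,
    phi: np.ndarray,
    genotype: str,
) -> IntensityTable:
    n = len(truth)
    a = np.log2(truth["abundance"].to_numpy())
    kap = truth["crosslink_eff"].to_numpy()
    units = _complex_units(truth)
    n_units = units.max() + 1 if n else 0

    log_phi_kap_c = np.log2(phi) + np.log2(kap) + math.log2(config.capture_eff)
    log_beta_c = _log2_or_minus_inf(config.nocl_background) + math.log2(config.capture_eff)

    samples: list[SampleMeta] = []
    columns: dict[str, np.ndarray] = {}
    for b in range(1, config.n_batches + 1):
        batch = f"B{b}"
        for rep in range(1, config.n_replicates + 1):
            eps = rng.normal(0.0, config.sigma_rep, n)  # shared culture noise
            u_wce = rng.normal(0.0, config.sigma_cplx, n_units)[units]
            u_ric = rng.normal(0.0, config.sigma_cplx, n_units)[units]
            for fraction, signal, u in (
                ("WCE", a, u_wce),
                ("RIC", a + log_phi_kap_c, u_ric),
            ):
                sid = f"{batch}_{genotype}_{fraction}_{rep}"
                offset = rng.normal(0.0, config.batch_effect_sd)
                columns[sid] = signal + offset + u + eps
                samples.append(SampleMeta(sid, fraction, genotype, rep, batch))
        if batch in config.nocl_batches:
            for rep in range(1, config.n_replicates + 1):
                eps2 = rng.normal(0.0, config.sigma_rep, n)  # separate cultures
                sid = f"{batch}_{genotype}_noCL_{rep}"
                offset = rng.normal(0.0, config.batch_effect_sd)
                columns[sid] = a + log_beta_c + offset + eps2
                samples.append(SampleMeta(sid, "noCL", genotype, rep, batch))

    values = pd.DataFrame(columns, index=truth["protein_id"])
    values = values.where(values >= config.detection_limit)  # left-censoring
    values.index.name = "protein_id"
    return IntensityTable(values, samples)


def draw_ground_truth(
    config: GeneratorConfig, seed: int | None = None
) -> pd.DataFrame:
    """Draw only the per-protein truth (abundance, phi, kappa, complexes).

    Uses the same stream position as the generators, so the truth returned
    here equals the one embedded in :func:`generate_experiment` /
    :func:`generate_mutant_pair` for the same seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return _draw_truth(config, rng)


def generate_experiment(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[IntensityTable, pd.DataFrame]:
    """Generate one single-genotype experiment and its ground truth.

    Returns the intensity table (RIC + WCE per replicate in every batch,
    noCL only in ``config.nocl_batches``) and the ground-truth table.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = _draw_truth(config, rng)
    table = _simulate_tables(
        config, truth, rng, truth["bound_fraction"].to_numpy(), config.genotype
    )
    return table, truth


def generate_mutant_pair(
    config: GeneratorConfig,
    mutant_spec: MutantSpec,
    seed: int | None = None,
    mutant_genotype: str = "mut",
) -> tuple[IntensityTable, IntensityTable, pd.DataFrame]:
    """Generate matched WT and mutant tables sharing abundance/kappa/complexes.

    The mutant's bound fraction is phi' = min(1, phi * 2**delta) for the
    affected proteins.  Both tables use a single triplicate batch (the
    paper-style comparative design, n = 3); noise draws are independent
    between genotypes.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cmp_config = replace(config, n_batches=1, nocl_batches=())
    truth = _draw_truth(cmp_config, rng)

    affected = np.zeros(len(truth), dtype=bool)
    if mutant_spec.protein_ids:
        unknown = set(mutant_spec.protein_ids) - set(truth["protein_id"])
        if unknown:
            raise ValueError(f"unknown protein ids in mutant spec: {sorted(unknown)[:5]}")
        affected |= truth["protein_id"].isin(mutant_spec.protein_ids).to_numpy()
    if mutant_spec.complex_ids:
        known = {c for c in truth["complex_id"] if c is not None}
        unknown = set(mutant_spec.complex_ids) - known
        if unknown:
            raise ValueError(f"unknown complex ids in mutant spec: {sorted(unknown)[:5]}")
        affected |= truth["complex_id"].isin(mutant_spec.complex_ids).to_numpy()

    phi_wt = truth["bound_fraction"].to_numpy()
    phi_mut = phi_wt.copy()
    phi_mut[affected] = np.minimum(1.0, phi_wt[affected] * 2.0 ** mutant_spec.delta)
    truth = truth.copy()
    truth.loc[affected, "mutant_effect"] = mutant_spec.delta
    truth["mutant_effect_realized"] = np.log2(phi_mut / phi_wt)

    wt = _simulate_tables(cmp_config, truth, rng, phi_wt, config.genotype)
    mut = _simulate_tables(cmp_config, truth, rng, phi_mut, mutant_genotype)
    return wt, mut, truth


# ---------------------------------------------------------------------------
# titration curves


@dataclass(frozen=True)
class FourPLTruth:
    ymin: float
    ymax: float
    kd: float
    n: float


def default_concentration_grid(
    top_nM: float = 1240.0, n_points: int = 13, dilution: float = 2.0
) -> np.ndarray:
    """13-point serial two-fold dilution from 1240 nM downward (~0.3 nM)."""
    return top_nM / dilution ** np.arange(n_points)


def generate_titration(
    params: FourPLTruth,
    concentrations: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate an anisotropy titration on the 4PL curve with Gaussian noise."""
    from .binding import four_pl

    x = (
        default_concentration_grid()
        if concentrations is None
        else np.asarray(list(concentrations), dtype=float)
    )
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    y = four_pl(x, params.ymin, params.ymax, params.kd, params.n)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, len(x))
    return pd.DataFrame({"concentration_nM": x, "anisotropy": y})


# ---------------------------------------------------------------------------
# annotation fixtures


@dataclass(frozen=True)
class PlantedDomain:
    """One synthetic Pfam-like domain planted on a truth stratum.

    stratum: "high" (high-phi proteins; expected classical_like),
    "low" (low-phi; expected substoichiometric), or "mixed"
    (half and half; expected adaptive).
    """

    pfam_id: str
    stratum: str
    n_members: int


@dataclass(frozen=True)
class DomainSpec:
    """Strata definitions for planted annotation fixtures.

    Strata are well-separated by construction: members come from the
    high-phi or low-phi tail of the bound-fraction mixture, with crosslink
    efficiency restricted to a central band (domain families have coherent
    crosslink chemistry, which keeps the within-domain ratio spread small),
    and are drawn from the most capturable proteins of each stratum
    (largest expected RIC intensity), since domain classes are only
    assessable on RIC-detected proteins.
    """

    domains: tuple[PlantedDomain, ...]
    phi_high_min: float = 0.2
    phi_low_max: float = 0.05
    kappa_range: tuple[float, float] = (0.08, 0.2)
    pool_factor: int = 3
    min_proteins: int = 4
    classical_pfam_id: str = "SYNCLASS_RRM"
    ribosome_go_term: str = "GO:0022626"


def expected_domain_class(domain: PlantedDomain, min_proteins: int = 4) -> str:
    if domain.n_members < min_proteins:
        return "unclassified"
    return {"high": "classical_like", "low": "substoichiometric", "mixed": "adaptive"}[
        domain.stratum
    ]


def generate_annotation_fixture(
    truth: pd.DataFrame,
    domain_spec: DomainSpec,
    config: GeneratorConfig,
    seed: int | None = None,
) -> tuple[AnnotationTable, pd.DataFrame]:
    """Plant synthetic nonclassical domains on truth strata.

    Returns the annotation table plus a table of planted domains with their
    expected class (by construction).  Every protein in the truth receives
    an annotation row (possibly empty).
    """
    rng = np.random.default_rng(seed)
    expected_ric = (
        np.log2(truth["abundance"].to_numpy())
        + np.log2(truth["bound_fraction"].to_numpy())
        + np.log2(truth["crosslink_eff"].to_numpy())
        + math.log2(config.capture_eff)
    )
    phi = truth["bound_fraction"].to_numpy()
    kappa = truth["crosslink_eff"].to_numpy()
    k_lo, k_hi = domain_spec.kappa_range
    in_band = (kappa >= k_lo) & (kappa <= k_hi)

    def stratum_pool(mask: np.ndarray, need: int) -> list[str]:
        ids = truth.index[mask]
        if len(ids) < need:
            raise ValueError(
                f"stratum pool too small ({len(ids)} eligible, {need} needed)"
            )
        order = np.argsort(-expected_ric[mask])  # most capturable first
        n_detectable = int((expected_ric[mask] >= config.detection_limit).sum())
        top = min(
            len(ids),
            min(domain_spec.pool_factor * need, max(need, n_detectable)),
        )
        return list(ids[order[:top]])

    need_high = sum(
        d.n_members if d.stratum == "high" else (d.n_members - d.n_members // 2)
        for d in domain_spec.domains
        if d.stratum in ("high", "mixed")
    )
    need_low = sum(
        d.n_members if d.stratum == "low" else d.n_members // 2
        for d in domain_spec.domains
        if d.stratum in ("low", "mixed")
    )
    high_pool = stratum_pool(in_band & (phi >= domain_spec.phi_high_min), need_high)
    low_pool = stratum_pool(in_band & (phi <= domain_spec.phi_low_max), need_low)

    pfam: dict[str, set[str]] = {p: set() for p in truth["protein_id"]}
    go: dict[str, set[str]] = {p: set() for p in truth["protein_id"]}

    expected_rows = []
    for dom in domain_spec.domains:
        if dom.stratum == "high":
            pools = [(high_pool, dom.n_members)]
        elif dom.stratum == "low":
            pools = [(low_pool, dom.n_members)]
        elif dom.stratum == "mixed":
            k = dom.n_members // 2
            pools = [(high_pool, dom.n_members - k), (low_pool, k)]
        else:
            raise ValueError(f"unknown stratum {dom.stratum!r}")
        for pool, k in pools:
            if k > len(pool):
                raise ValueError(
                    f"stratum {dom.stratum!r} pool too small for {dom.pfam_id} "
                    f"({k} requested, {len(pool)} eligible)"
                )
            members = rng.choice(len(pool), size=k, replace=False)
            for m in members:
                pfam[pool[m]].add(dom.pfam_id)
        expected_rows.append(
            {
                "pfam_id": dom.pfam_id,
                "stratum": dom.stratum,
                "n_members": dom.n_members,
                "expected_class": expected_domain_class(dom, domain_spec.min_proteins),
            }
        )

    # distractors: a few high-phi proteins *outside* the planted pools carry
    # a classical RBD, and a few others the cytosolic-ribosome GO term; both
    # must be excluded from nonclassical domain statistics downstream
    pooled = set(high_pool) | set(low_pool)
    outside = [
        p
        for p in truth.index[phi >= domain_spec.phi_high_min]
        if p not in pooled
    ]
    for tag in ("classical", "ribosome"):
        k = min(5, len(outside))
        chosen = rng.choice(len(outside), size=k, replace=False)
        for m in sorted(chosen, reverse=True):
            p = outside.pop(m)
            if tag == "classical":
                pfam[p].add(domain_spec.classical_pfam_id)
            else:
                go[p].add(domain_spec.ribosome_go_term)

    ann = AnnotationTable(
        pfam={p: frozenset(v) for p, v in pfam.items()},
        go={p: frozenset(v) for p, v in go.items()},
        classical_ids=frozenset({domain_spec.classical_pfam_id}),
        nonclassical_ids=frozenset(d.pfam_id for d in domain_spec.domains),
    )
    return ann, pd.DataFrame(expected_rows)


def default_domain_spec(n_per_class: int = 8, members: int = 6) -> DomainSpec:
    """A well-separated planted-domain design: n domains per class."""
    domains = []
    for i in range(1, n_per_class + 1):
        domains.append(PlantedDomain(f"SYNHI_{i:02d}", "high", members))
        domains.append(PlantedDomain(f"SYNLO_{i:02d}", "low", members))
        domains.append(PlantedDomain(f"SYNMX_{i:02d}", "mixed", members))
    return DomainSpec(domains=tuple(domains))
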