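"""Synthetic questionnaire cohorts with planted trait/subject structure.

The generator emulates the statistical structure the analysis pipeline
assumes in the study population: two anticorrelated *trait clusters*
(a "positive" cluster of openness, extraversion, conscientiousness and
agreeableness, and a "negative" cluster of neuroticism, shyness,
alexithymia, autism, anxiety, depression and sensory processing
sensitivity), three *subject groups* (positive / moderate / negative
scorers), and one "spectrum" trait whose subdomains load on opposite
clusters (sensory processing sensitivity, whose aesthetic-sensitivity
subdomain sits among the positive traits next to openness).

Response model
--------------
Two standard-normal cluster factors ``c1, c2`` have correlation
``between_cluster_corr`` (negative).  Each trait ``t`` in cluster ``k``
gets a factor

    f_t = sqrt(w_t) * c_k + sqrt(1 - w_t) * u_t,      u_t ~ N(0, 1) iid,

where ``w_t`` is the trait's cluster coupling (``within_cluster_corr``
unless overridden per trait; two traits within one cluster then correlate
at ``sqrt(w_t w_s)``).  An item of trait ``t`` is

    y = loading * f + noise_sd * eps,

where ``f`` is the trait factor, or for a subdomain with
``cluster_override`` a private factor coupled to the overridden cluster,
or for a subdomain with ``mix_with`` the named neighbor trait's factor
(items then intermix with that neighbor, which is how the spectrum
subdomain is planted).  ``noise_sd=None`` standardizes each item to unit
variance (noise sd ``sqrt(1 - loading**2)``).

Subject group ``g`` adds mean shifts to the two cluster factors and,
optionally, to individual trait factors (the moderate group's prominent
autism score).  Continuous scores are discretized to each item's Likert
range by equiprobable normal-quantile thresholds, which keeps marginals
balanced and preserves the sign structure of correlations.

Everything is driven by one seed through per-stage substreams, so the
same parameters always produce bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .schema import Instrument, Item, QuestionnaireSchema
from .scoring import ResponseMatrix

__all__ = [
    "SubdomainSpec",
    "TraitSpec",
    "GroupSpec",
    "GeneratorParams",
    "SyntheticGroundTruth",
    "generate_cohort",
    "generate_pbi",
    "population_correlations",
    "population_trait_correlations",
    "build_schema",
    "params_from_yaml",
    "params_to_yaml",
    "study_like_params",
    "toy_params",
]


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class SubdomainSpec:
    name: str
    n_items: int
    cluster_override: int | None = None
    mix_with: str | None = None  # plant items on this trait's factor


@dataclass(frozen=True)
class TraitSpec:
    name: str
    cluster: int  # 1 or 2
    n_items: int
    loading: float = 0.7
    scale: tuple[int, int] = (1, 5)
    subdomains: tuple[SubdomainSpec, ...] = ()
    cluster_loading: float | None = None  # per-trait w_t; defaults to within_cluster_corr


@dataclass(frozen=True)
class GroupSpec:
    proportion: float
    shift_cluster1: float = 0.0
    shift_cluster2: float = 0.0
    trait_shifts: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GeneratorParams:
    traits: tuple[TraitSpec, ...]
    n_subjects: int = 837
    within_cluster_corr: float = 0.45
    between_cluster_corr: float = -0.4
    subject_groups: tuple[GroupSpec, ...] = (GroupSpec(1.0),)
    noise_sd: float | None = None  # None => unit-variance items
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.traits:
            raise GeneratorError("need at least one trait")
        props = [g.proportion for g in self.subject_groups]
        if abs(sum(props) - 1.0) > 1e-9:
            raise GeneratorError(f"group proportions must sum to 1, got {sum(props)}")
        if not abs(self.between_cluster_corr) < 1.0:
            raise GeneratorError("|between_cluster_corr| must be < 1")
        if not 0.0 <= self.within_cluster_corr < 1.0:
            raise GeneratorError("within_cluster_corr must be in [0, 1)")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise GeneratorError("duplicate trait names")
        for t in self.traits:
            if t.cluster not in (1, 2):
                raise GeneratorError(f"trait {t.name!r}: cluster must be 1 or 2")
            if not 0.0 < t.loading <= 1.0:
                raise GeneratorError(f"trait {t.name!r}: loading must be in (0, 1]")
            w = t.cluster_loading
            if w is not None and not 0.0 <= w < 1.0:
                raise GeneratorError(f"trait {t.name!r}: cluster_loading must be in [0, 1)")
            n_sub = sum(s.n_items for s in t.subdomains)
            if n_sub > t.n_items:
                raise GeneratorError(f"trait {t.name!r}: subdomain items exceed n_items")
            for s in t.subdomains:
                if s.mix_with is not None and s.mix_with not in names:
                    raise GeneratorError(f"subdomain {s.name!r}: unknown mix_with trait {s.mix_with!r}")
                if s.cluster_override is not None and s.cluster_override not in (1, 2):
                    raise GeneratorError(f"subdomain {s.name!r}: cluster_override must be 1 or 2")


@dataclass
class SyntheticGroundTruth:
    """Planted labels plus the population correlation matrix of the items."""

    trait_cluster: dict[str, int]
    item_subdomain: dict[str, str | None]
    item_cluster: dict[str, int]
    subject_group: dict[str, int]
    population_corr: pd.DataFrame


# ---------------------------------------------------------------------------
# linear factor bookkeeping
# ---------------------------------------------------------------------------


@dataclass
class _LinComb:
    """A Gaussian variable as a·(c1,c2) + sum_u b_u·u + independent noise.

    ``means`` holds the per-group mean.  Covariances (including the
    between-group mean-mixture term) follow in closed form.
    """

    a: np.ndarray  # shape (2,)
    u: dict[str, float]
    noise_var: float
    means: np.ndarray  # shape (n_groups,)

    def scaled(self, lam: float, extra_noise_var: float = 0.0) -> "_LinComb":
        return _LinComb(
            lam * self.a,
            {k: lam * v for k, v in self.u.items()},
            lam * lam * self.noise_var + extra_noise_var,
            lam * self.means,
        )

    @staticmethod
    def total_cov(x: "_LinComb", y: "_LinComb", sigma_c: np.ndarray, props: np.ndarray, same: bool) -> float:
        cov_w = float(x.a @ sigma_c @ y.a)
        cov_w += sum(bx * y.u.get(k, 0.0) for k, bx in x.u.items())
        if same:
            cov_w += x.noise_var
        # between-group (mean mixture) component
        mx, my = x.means, y.means
        cov_b = float(props @ (mx * my) - (props @ mx) * (props @ my))
        return cov_w + cov_b


def _factor_model(params: GeneratorParams):
    """Build per-item _LinComb representations and label maps."""
    props = np.array([g.proportion for g in params.subject_groups])
    shifts = np.array(
        [[g.shift_cluster1, g.shift_cluster2] for g in params.subject_groups]
    )  # (G, 2)

    trait_factors: dict[str, _LinComb] = {}
    factor_cluster: dict[str, int] = {}
    for t in params.traits:
        w = params.within_cluster_corr if t.cluster_loading is None else t.cluster_loading
        a = np.zeros(2)
        a[t.cluster - 1] = np.sqrt(w)
        means = np.sqrt(w) * shifts[:, t.cluster - 1] + np.array(
            [g.trait_shifts.get(t.name, 0.0) for g in params.subject_groups]
        )
        trait_factors[t.name] = _LinComb(a, {f"u:{t.name}": np.sqrt(1.0 - w)}, 0.0, means)
        factor_cluster[t.name] = t.cluster

    items: list[dict] = []
    for t in params.traits:
        w = params.within_cluster_corr if t.cluster_loading is None else t.cluster_loading
        sub_of: list[tuple[str | None, _LinComb, int]] = []
        for s in t.subdomains:
            if s.mix_with is not None:
                fac = trait_factors[s.mix_with]
                cl = factor_cluster[s.mix_with]
            elif s.cluster_override is not None:
                a = np.zeros(2)
                a[s.cluster_override - 1] = np.sqrt(w)
                means = np.sqrt(w) * shifts[:, s.cluster_override - 1]
                fac = _LinComb(a, {f"u:{t.name}.{s.name}": np.sqrt(1.0 - w)}, 0.0, means)
                cl = s.cluster_override
            else:
                fac, cl = trait_factors[t.name], t.cluster
            sub_of.extend((s.name, fac, cl) for _ in range(s.n_items))
        n_uncat = t.n_items - len(sub_of)
        sub_of.extend((None, trait_factors[t.name], t.cluster) for _ in range(n_uncat))
        lam = t.loading
        s_noise = params.noise_sd if params.noise_sd is not None else float(np.sqrt(max(1.0 - lam * lam, 0.0)))
        for q, (sub, fac, cl) in enumerate(sub_of, start=1):
            items.append(
                {
                    "id": f"{t.name}_q{q:02d}",
                    "trait": t.name,
                    "subdomain": sub,
                    "cluster": cl,
                    "lincomb": fac.scaled(lam, s_noise**2),
                    "factor": fac,
                    "loading": lam,
                    "noise_sd": s_noise,
                    "scale": t.scale,
                }
            )

    b = params.between_cluster_corr
    sigma_c = np.array([[1.0, b], [b, 1.0]])
    try:
        np.linalg.cholesky(sigma_c)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by validation
        raise GeneratorError("infeasible cluster-factor correlation (non-PSD)") from exc
    return items, trait_factors, sigma_c, props


def _corr_from_lincombs(lcs: Sequence[_LinComb], sigma_c: np.ndarray, props: np.ndarray) -> np.ndarray:
    n = len(lcs)
    cov = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            cov[i, j] = cov[j, i] = _LinComb.total_cov(lcs[i], lcs[j], sigma_c, props, same=(i == j))
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise GeneratorError("infeasible correlation structure (non-PSD)")
    return corr


def population_correlations(params: GeneratorParams) -> pd.DataFrame:
    """Closed-form correlation matrix of the continuous (pre-discretization) items.

    Includes both the within-group factor covariance and the
    between-group component induced by group mean shifts, so the sample
    correlation matrix of a large cohort converges to this matrix.
    """
    items, _, sigma_c, props = _factor_model(params)
    ids = [it["id"] for it in items]
    corr = _corr_from_lincombs([it["lincomb"] for it in items], sigma_c, props)
    return pd.DataFrame(corr, index=ids, columns=ids)


def population_trait_correlations(params: GeneratorParams) -> pd.DataFrame:
    """Closed-form correlation matrix of the continuous trait *sum scores*."""
    items, _, sigma_c, props = _factor_model(params)
    trait_names = [t.name for t in params.traits]
    combs = []
    for name in trait_names:
        parts = [it["lincomb"] for it in items if it["trait"] == name]
        a = np.sum([p.a for p in parts], axis=0)
        u: dict[str, float] = {}
        for p in parts:
            for k, v in p.u.items():
                u[k] = u.get(k, 0.0) + v
        noise = sum(p.noise_var for p in parts)
        means = np.sum([p.means for p in parts], axis=0)
        combs.append(_LinComb(a, u, noise, means))
    corr = _corr_from_lincombs(combs, sigma_c, props)
    return pd.DataFrame(corr, index=trait_names, columns=trait_names)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def _substreams(params: GeneratorParams):
    children = np.random.SeedSequence(params.seed).spawn(6)
    return {
        name: np.random.default_rng(ss)
        for name, ss in zip(("groups", "clusters", "factors", "noise", "meta", "pbi"), children)
    }


def _assign_groups(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    n = params.n_subjects
    props = np.array([g.proportion for g in params.subject_groups])
    counts = np.floor(props * n).astype(int)
    # largest-remainder rounding
    rem = props * n - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    labels = np.repeat(np.arange(len(props)), counts)
    return rng.permutation(labels)


def _sample_cluster_factors(params: GeneratorParams, rngs) -> tuple[np.ndarray, np.ndarray]:
    """Group labels and the (shifted) cluster factors ``c`` (n x 2)."""
    groups = _assign_groups(params, rngs["groups"])
    b = params.between_cluster_corr
    L = np.linalg.cholesky(np.array([[1.0, b], [b, 1.0]]))
    c = rngs["clusters"].standard_normal((params.n_subjects, 2)) @ L.T
    shifts = np.array([[g.shift_cluster1, g.shift_cluster2] for g in params.subject_groups])
    c += shifts[groups]
    return groups, c


def generate_cohort(params: GeneratorParams) -> tuple[ResponseMatrix, SyntheticGroundTruth]:
    """Sample a cohort: discretized Likert responses plus planted ground truth.

    Identical parameters (including the seed) give bit-identical output.
    """
    items, trait_factors, sigma_c, props = _factor_model(params)
    rngs = _substreams(params)
    n = params.n_subjects
    groups, c = _sample_cluster_factors(params, rngs)

    # trait / private-subdomain factors, sampled in declaration order
    u_draws: dict[str, np.ndarray] = {}

    def u_for(name: str) -> np.ndarray:
        if name not in u_draws:
            u_draws[name] = rngs["factors"].standard_normal(n)
        return u_draws[name]

    trait_shift_mat = {
        t.name: np.array([g.trait_shifts.get(t.name, 0.0) for g in params.subject_groups])
        for t in params.traits
    }

    factor_values: dict[int, np.ndarray] = {}

    def realize(fac: _LinComb, trait: str | None) -> np.ndarray:
        key = id(fac)
        if key not in factor_values:
            val = c @ fac.a
            for uname, bcoef in fac.u.items():
                val = val + bcoef * u_for(uname)
            if trait is not None and trait in trait_shift_mat:
                val = val + trait_shift_mat[trait][groups]
            factor_values[key] = val
        return factor_values[key]

    # realize trait factors first (with their shifts), in trait order
    for t in params.traits:
        realize(trait_factors[t.name], t.name)

    data = {}
    item_subdomain: dict[str, str | None] = {}
    item_cluster: dict[str, int] = {}
    for it in items:
        f = realize(it["factor"], None)
        y = it["loading"] * f + it["noise_sd"] * rngs["noise"].standard_normal(n)
        lo, hi = it["scale"]
        levels = hi - lo + 1
        lc: _LinComb = it["lincomb"]
        mu = float(props @ lc.means)
        var = _LinComb.total_cov(lc, lc, sigma_c, props, same=True)
        qs = stats.norm.ppf(np.arange(1, levels) / levels, loc=mu, scale=np.sqrt(var))
        data[it["id"]] = lo + np.searchsorted(qs, y, side="left")
        item_subdomain[it["id"]] = it["subdomain"]
        item_cluster[it["id"]] = it["cluster"]

    subject_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    values = pd.DataFrame(data, index=pd.Index(subject_ids, name="subject"))
    rng_meta = rngs["meta"]
    age = np.clip(np.round(rng_meta.normal(28.12, 9.64, n)), 18, 75).astype(int)
    sex = np.where(rng_meta.random(n) < 0.6857, "female", "male")
    metadata = pd.DataFrame(
        {"age": age, "sex": sex, "excluded": False, "exclusion_reason": None},
        index=values.index,
    )
    truth = SyntheticGroundTruth(
        trait_cluster={t.name: t.cluster for t in params.traits},
        item_subdomain=item_subdomain,
        item_cluster=item_cluster,
        subject_group={sid: int(g) + 1 for sid, g in zip(subject_ids, groups)},
        population_corr=population_correlations(params),
    )
    return ResponseMatrix(values, metadata), truth


def generate_pbi(
    params: GeneratorParams,
    care_corr: float = -0.3,
    overprot_corr: float = 0.3,
) -> pd.DataFrame:
    """Parental-bonding scores (mother and father forms) tied to the cohort.

    Each form's care score correlates ``care_corr`` with the negative
    cluster factor ``c2`` (good parental care lowers negative-trait
    scores) and the overprotection score correlates ``overprot_corr``
    with it.  The same seed substreams as :func:`generate_cohort` are
    used, so the returned scores line up subject-by-subject with the
    cohort generated from the same parameters.
    """
    if not (abs(care_corr) < 1 and abs(overprot_corr) < 1):
        raise GeneratorError("|care_corr| and |overprot_corr| must be < 1")
    rngs = _substreams(params)
    _, c = _sample_cluster_factors(params, rngs)
    rng = rngs["pbi"]
    n = params.n_subjects
    out = {}
    for dim, rho in (("care", care_corr), ("overprotection", overprot_corr)):
        for form in ("mother", "father"):
            eps = rng.standard_normal(n)
            out[f"{form}_{dim}"] = rho * c[:, 1] + np.sqrt(1.0 - rho * rho) * eps
    subject_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    return pd.DataFrame(out, index=pd.Index(subject_ids, name="subject"))


def build_schema(params: GeneratorParams) -> QuestionnaireSchema:
    """Questionnaire schema matching a generated cohort (one instrument per trait).

    Generated responses are already keyed, so no item is reverse-flagged.
    """
    items, *_ = _factor_model(params)
    insts = []
    for t in params.traits:
        t_items = tuple(
            Item(id=it["id"], subdomain=it["subdomain"]) for it in items if it["trait"] == t.name
        )
        insts.append(
            Instrument(name=t.name, trait=t.name, items=t_items, scale=t.scale, scoring="sum")
        )
    return QuestionnaireSchema(tuple(insts))


# ---------------------------------------------------------------------------
# preset serialization
# ---------------------------------------------------------------------------


def params_to_yaml(params: GeneratorParams, path) -> None:
    """Write generator parameters as a YAML preset."""
    import dataclasses
    from pathlib import Path

    import yaml

    d = dataclasses.asdict(params)
    for t in d["traits"]:
        t["scale"] = list(t["scale"])
        t["subdomains"] = [dict(s) for s in t["subdomains"]]
    for g in d["subject_groups"]:
        g["trait_shifts"] = dict(g["trait_shifts"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def params_from_yaml(path) -> GeneratorParams:
    """Load a YAML preset written by :func:`params_to_yaml`."""
    from pathlib import Path

    import yaml

    d = yaml.safe_load(Path(path).read_text())
    traits = tuple(
        TraitSpec(
            name=t["name"],
            cluster=t["cluster"],
            n_items=t["n_items"],
            loading=t.get("loading", 0.7),
            scale=tuple(t.get("scale", (1, 5))),
            subdomains=tuple(SubdomainSpec(**s) for s in t.get("subdomains", ())),
            cluster_loading=t.get("cluster_loading"),
        )
        for t in d["traits"]
    )
    groups = tuple(
        GroupSpec(
            proportion=g["proportion"],
            shift_cluster1=g.get("shift_cluster1", 0.0),
            shift_cluster2=g.get("shift_cluster2", 0.0),
            trait_shifts=g.get("trait_shifts", {}),
        )
        for g in d.get("subject_groups", ({"proportion": 1.0},))
    )
    return GeneratorParams(
        traits=traits,
        n_subjects=d.get("n_subjects", 837),
        within_cluster_corr=d.get("within_cluster_corr", 0.45),
        between_cluster_corr=d.get("between_cluster_corr", -0.4),
        subject_groups=groups,
        noise_sd=d.get("noise_sd"),
        seed=d.get("seed", 0),
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def study_like_params(seed: int = 0, n_subjects: int = 837) -> GeneratorParams:
    """The default study-like preset: 11 traits / 210 items / 837 subjects.

    Cluster 1 ("positive"): openness, extraversion, conscientiousness,
    agreeableness.  Cluster 2 ("negative"): neuroticism, shyness,
    alexithymia, autism, anxiety, depression, SPS.  Conscientiousness and
    neuroticism get a stronger cluster coupling (the hub traits).  The
    SPS instrument carries the three subdomains, with the 7
    aesthetic-sensitivity items planted among the openness items
    (``mix_with``) so they fall in the opposite cluster, and the autism
    instrument an 8-item attention-to-detail subdomain coupled to the
    positive cluster.  Subject groups: positive (39.2%, shifted up on
    cluster 1 and down on cluster 2), moderate (35.4%, no cluster shift
    but a distinct signature of raised autism and extraversion factors
    that makes it identifiable under correlation distance), negative
    (25.4%, the mirror image of positive).
    """
    big5 = dict(n_items=12, scale=(1, 5), loading=0.7)
    traits = (
        TraitSpec("openness", 1, **big5),
        TraitSpec("extraversion", 1, **big5),
        TraitSpec("conscientiousness", 1, cluster_loading=0.65, **big5),
        TraitSpec("agreeableness", 1, **big5),
        TraitSpec("neuroticism", 2, cluster_loading=0.65, **big5),
        TraitSpec(
            "SPS",
            2,
            n_items=27,
            scale=(1, 7),
            loading=0.7,
            subdomains=(
                SubdomainSpec("AES", 7, mix_with="openness"),
                SubdomainSpec("EOE", 12),
                SubdomainSpec("LST", 6),
            ),
        ),
        TraitSpec("shyness", 2, n_items=14, scale=(1, 5), loading=0.7),
        TraitSpec(
            "alexithymia",
            2,
            n_items=20,
            scale=(1, 5),
            loading=0.7,
            subdomains=(
                SubdomainSpec("identify_feelings", 7),
                SubdomainSpec("describe_feelings", 5),
                SubdomainSpec("external_thinking", 8),
            ),
        ),
        TraitSpec(
            "autism",
            2,
            n_items=50,
            scale=(1, 4),
            loading=0.7,
            subdomains=(
                SubdomainSpec("social_skills", 12),
                SubdomainSpec("attention_to_detail", 8, cluster_override=1),
                SubdomainSpec("communication", 12),
            ),
        ),
        TraitSpec("anxiety", 2, n_items=21, scale=(0, 3), loading=0.7),
        TraitSpec("depression", 2, n_items=18, scale=(0, 5), loading=0.7),
    )
    groups = (
        GroupSpec(328 / 837, shift_cluster1=3.0, shift_cluster2=-3.0),
        GroupSpec(296 / 837, trait_shifts={"autism": 5.0, "extraversion": 4.0}),
        GroupSpec(213 / 837, shift_cluster1=-3.0, shift_cluster2=3.0),
    )
    return GeneratorParams(
        traits=traits,
        n_subjects=n_subjects,
        within_cluster_corr=0.45,
        between_cluster_corr=-0.4,
        subject_groups=groups,
        seed=seed,
    )


def toy_params(seed: int = 0, n_subjects: int = 300) -> GeneratorParams:
    """A small two-cluster preset (4 traits, 20 items) for quick tests."""
    traits = (
        TraitSpec("pos_a", 1, n_items=5, scale=(1, 5)),
        TraitSpec("pos_b", 1, n_items=5, scale=(1, 5)),
        TraitSpec("neg_a", 2, n_items=5, scale=(1, 5)),
        TraitSpec("neg_b", 2, n_items=5, scale=(1, 7)),
    )
    groups = (
        GroupSpec(0.4, 1.6, -1.6),
        GroupSpec(0.3),
        GroupSpec(0.3, -1.6, 1.6),
    )
    return GeneratorParams(
        traits=traits, n_subjects=n_subjects, subject_groups=groups, seed=seed
    )
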