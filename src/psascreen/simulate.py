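"""Synthetic PSO/PSA cohort generation from published per-group summaries.

The generator emulates two cohorts — a US survey-based cohort
(``nhanes_like``, 574 psoriasis / 145 psoriatic-arthritis subjects) and a
Chinese hospital cohort (``chinese_like``, 98 / 37) — by sampling each
variable from a parametric family fitted to the printed per-group summary
statistics (mean ± SD, median with quartiles, or category counts).

Skewed variables (printed as median (Q1, Q3)) are sampled as the exponential
of a two-piece normal whose lower and upper log-scale standard deviations are
fitted separately to the two printed quartiles, so the sampled distribution's
quartiles match the printed triple exactly; when the printed quartiles are
symmetric on the log scale this reduces to an ordinary lognormal with the
parameters returned by :func:`fit_lognormal_from_quartiles`.  Symmetric
variables (mean ± SD) are truncated normal with a positivity floor.
Dependence between variables is independence by default, or a Gaussian
copula with a user-supplied latent correlation matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "Z75",
    "VariableSpec",
    "GeneratorConfig",
    "fit_lognormal_from_quartiles",
    "load_catalogue",
    "catalogue_sizes",
    "generate_group",
    "generate_study",
    "inject_missingness",
    "sample_psaii_components",
    "PSAII_COMPONENTS",
]

#: Standard normal upper-quartile deviate, z such that Phi(z) = 0.75.
Z75 = 0.6744897501960817

#: The four serum components of the PSAII index.
PSAII_COMPONENTS = ("lymphocyte_pct", "crp", "neutrophil_count", "eosinophil_count")

_FAMILIES = ("normal", "lognormal", "bernoulli", "categorical")
_ROLES = ("demographic", "comorbidity", "serum")


def fit_lognormal_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Fit lognormal parameters (mu, sigma) to a printed quartile triple.

    mu = ln(median); sigma = (ln q3 - ln q1) / (2 * z0.75).  The implied
    distribution reproduces the printed quartiles exactly when
    q1 * q3 = median**2 and approximates them otherwise.

    Raises
    ------
    ValueError
        If any input is non-positive or the ordering q1 <= median <= q3
        is violated.
    """
    if median <= 0 or q1 <= 0 or q3 <= 0:
        raise ValueError(
            f"lognormal fit requires positive quartiles, got ({median}, {q1}, {q3})"
        )
    if not (q1 <= median <= q3):
        raise ValueError(f"quartiles out of order: q1={q1}, median={median}, q3={q3}")
    mu = math.log(median)
    sigma = (math.log(q3) - math.log(q1)) / (2.0 * Z75)
    return mu, sigma


@dataclass
class VariableSpec:
    """Distributional description of one cohort variable.

    ``params`` maps group name ('pso' / 'psa') to that group's parameter
    dict: {mean, sd} for normal, {median, q1, q3} for lognormal, {p} for
    bernoulli, {probs} for categorical (codes 1..K in category order).
    """

    name: str
    role: str
    family: str
    params: Mapping[str, Mapping]
    units: str = ""
    floor: float = 0.01
    ceiling: float | None = None
    categories: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r} for {self.name}")
        if self.role not in _ROLES:
            raise ValueError(f"unknown role {self.role!r} for {self.name}")
        for group, p in self.params.items():
            if self.family == "lognormal":
                m, q1, q3 = p["median"], p["q1"], p["q3"]
                if not (0 < q1 <= m <= q3):
                    raise ValueError(
                        f"{self.name}/{group}: need 0 < q1 <= median <= q3, "
                        f"got ({q1}, {m}, {q3})"
                    )
            elif self.family == "normal":
                if p["sd"] < 0:
                    raise ValueError(f"{self.name}/{group}: sd must be >= 0")
            elif self.family == "bernoulli":
                if not 0.0 <= p["p"] <= 1.0:
                    raise ValueError(f"{self.name}/{group}: prevalence outside [0, 1]")
            else:
                probs = np.asarray(p["probs"], dtype=float)
                if abs(probs.sum() - 1.0) > 1e-9:
                    raise ValueError(
                        f"{self.name}/{group}: category probabilities sum to "
                        f"{probs.sum()}, expected 1"
                    )

    def sample_from_normal(self, z: np.ndarray, group: str) -> np.ndarray:
        """Map standard-normal draws ``z`` to this variable for ``group``.

        Driving every family through a standard-normal vector makes the
        Gaussian copula a matter of correlating the z's.
        """
        if group not in self.params:
            raise KeyError(f"variable {self.name!r} has no parameters for group {group!r}")
        p = self.params[group]
        if self.family == "normal":
            lo, hi = self.floor, self.ceiling if self.ceiling is not None else np.inf
            if p["sd"] == 0:
                return np.full(z.shape, float(np.clip(p["mean"], lo, hi)))
            a = (lo - p["mean"]) / p["sd"]
            b = (hi - p["mean"]) / p["sd"]
            u = stats.norm.cdf(z)
            return stats.truncnorm.ppf(u, a, b, loc=p["mean"], scale=p["sd"])
        if self.family == "lognormal":
            mu = math.log(p["median"])
            s_lo = (mu - math.log(p["q1"])) / Z75
            s_hi = (math.log(p["q3"]) - mu) / Z75
            x = np.exp(mu + np.where(z < 0, s_lo, s_hi) * z)
            if self.ceiling is not None:
                x = np.minimum(x, self.ceiling)
            return x
        u = stats.norm.cdf(z)
        if self.family == "bernoulli":
            return (u < p["p"]).astype(float)
        cum = np.cumsum(np.asarray(p["probs"], dtype=float))
        return (np.searchsorted(cum, u, side="right") + 1).astype(float)


@dataclass
class GeneratorConfig:
    """Cohort sizes, dependence model and seed for a synthetic study."""

    nhanes_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"pso": 574, "psa": 145}
    )
    chinese_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"pso": 98, "psa": 37}
    )
    dependence: str = "independence"
    rank_corr: pd.DataFrame | None = None
    screening_aux: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for sizes in (self.nhanes_sizes, self.chinese_sizes):
            for g, n in sizes.items():
                if n < 0:
                    raise ValueError(f"negative group size for {g}: {n}")
        if self.dependence not in ("independence", "gaussian-copula"):
            raise ValueError(f"unknown dependence model {self.dependence!r}")
        if self.dependence == "gaussian-copula":
            if self.rank_corr is None:
                raise ValueError("gaussian-copula dependence requires rank_corr")
            r = np.asarray(self.rank_corr, dtype=float)
            if not np.allclose(r, r.T) or not np.allclose(np.diag(r), 1.0):
                raise ValueError("rank_corr must be symmetric with unit diagonal")
            if np.linalg.eigvalsh(r).min() < -1e-10:
                raise ValueError("rank_corr must be positive semi-definite")


def _catalogue_raw() -> dict:
    path = resources.files("psascreen.data") / "cohort_catalogue.yaml"
    with path.open("r") as fh:
        return yaml.safe_load(fh)


def load_catalogue(cohort: str = "nhanes_like") -> list[VariableSpec]:
    """Load the shipped per-group summary catalogue for one cohort."""
    raw = _catalogue_raw()
    if cohort not in raw:
        raise KeyError(f"unknown cohort {cohort!r}; available: {sorted(raw)}")
    sizes = raw[cohort]["sizes"]
    specs = []
    for name, entry in raw[cohort]["variables"].items():
        family = entry["family"]
        params: dict[str, dict] = {}
        for group in ("pso", "psa"):
            p = dict(entry[group])
            if family == "bernoulli":
                p = {"p": p["count"] / p["n"]}
            elif family == "categorical":
                counts = np.asarray(p["counts"], dtype=float)
                total = counts.sum() if counts.sum() > 0 else sizes[group]
                p = {"probs": (counts / total).tolist()}
            params[group] = p
        specs.append(
            VariableSpec(
                name=name,
                role=entry["role"],
                family=family,
                params=params,
                units=entry.get("units", ""),
                ceiling=entry.get("ceiling"),
                categories=entry.get("categories"),
            )
        )
    return specs


def catalogue_sizes(cohort: str = "nhanes_like") -> dict[str, int]:
    """Published group sizes for one catalogue cohort."""
    return dict(_catalogue_raw()[cohort]["sizes"])


def _draw_z(rng: np.random.Generator, n: int, specs: Sequence[VariableSpec],
            config: GeneratorConfig | None) -> np.ndarray:
    k = len(specs)
    z = rng.standard_normal((n, k))
    if config is not None and config.dependence == "gaussian-copula":
        corr = config.rank_corr
        names = [s.name for s in specs]
        r = corr.loc[names, names].to_numpy(dtype=float)
        # small jitter keeps Cholesky defined for semi-definite matrices
        chol = np.linalg.cholesky(r + 1e-10 * np.eye(k))
        z = z @ chol.T
    return z


def generate_group(
    specs: Sequence[VariableSpec],
    group: str,
    n: int,
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    cohort: str = "nhanes_like",
) -> pd.DataFrame:
    """Sample ``n`` subjects of one outcome group ('pso' or 'psa')."""
    if group not in ("pso", "psa"):
        raise ValueError(f"group must be 'pso' or 'psa', got {group!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed if config is not None else 0)
    z = _draw_z(rng, n, specs, config)
    data = {
        spec.name: spec.sample_from_normal(z[:, j], group)
        for j, spec in enumerate(specs)
    }
    df = pd.DataFrame(data, dtype=float)
    df.insert(0, "label", int(group == "psa"))
    df.insert(1, "cohort", cohort)
    return df


def _screening_aux(df: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Attach synthetic arthralgia and ToPAS columns to exercise triage.

    These columns are invented study plumbing (no published marginal exists
    for them); arthralgia is more common and ToPAS scores higher in the PSA
    group, which is all the triage rule needs structurally.
    """
    df = df.copy()
    is_psa = df["label"].to_numpy() == 1
    p_arthralgia = np.where(is_psa, 0.85, 0.25)
    df["arthralgia"] = (rng.random(len(df)) < p_arthralgia).astype(int)
    lam = np.where(is_psa, 8.0, 3.0)
    df["topas"] = np.minimum(rng.poisson(lam), 12).astype(int)
    return df


def generate_study(
    config: GeneratorConfig | None = None,
    specs: Mapping[str, Sequence[VariableSpec]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full two-cohort study (nhanes_like, chinese_like)."""
    config = config if config is not None else GeneratorConfig()
    if specs is None:
        specs = {c: load_catalogue(c) for c in ("nhanes_like", "chinese_like")}
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=4)
    tables = []
    for i, (cohort, sizes) in enumerate(
        (("nhanes_like", config.nhanes_sizes), ("chinese_like", config.chinese_sizes))
    ):
        parts = []
        for j, group in enumerate(("pso", "psa")):
            rng = np.random.default_rng(seeds[2 * i + j])
            parts.append(
                generate_group(specs[cohort], group, sizes[group], config, rng, cohort)
            )
        df = pd.concat(parts, ignore_index=True)
        df.insert(0, "subject_id", [f"{cohort}-{k:05d}" for k in range(len(df))])
        if config.screening_aux:
            df = _screening_aux(df, np.random.default_rng(seeds[2 * i + 1] + 1))
        tables.append(df)
    return tables[0], tables[1]


def inject_missingness(
    table: pd.DataFrame, rate: float, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Blank each non-label numeric cell independently with probability ``rate``.

    Returns the gapped table and a boolean mask of blanked cells (the truth
    withheld for imputation testing).  ``rate`` must be below 1/3, otherwise
    whole subjects would routinely trip the missingness exclusion rule.
    """
    if not 0.0 <= rate < 1.0 / 3.0:
        raise ValueError(f"missingness rate must be in [0, 1/3), got {rate}")
    rng = np.random.default_rng(seed)
    protected = {"label", "subject_id", "cohort"}
    cols = [c for c in table.columns if c not in protected]
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    out = table.copy()
    if rate > 0:
        blank = rng.random((len(table), len(cols))) < rate
        for j, c in enumerate(cols):
            out.loc[blank[:, j], c] = np.nan
            mask[c] = blank[:, j]
    return out, mask


def sample_psaii_components(
    cohort: str, n_pso: int, n_psa: int, seed: int = 0
) -> pd.DataFrame:
    """Sample only the four PSAII components using symmetric lognormal fits.

    This is the reduced generator behind the headline simulation checks: for
    the nhanes_like cohort all four components are lognormal with parameters
    from :func:`fit_lognormal_from_quartiles`; for the chinese_like cohort
    lymphocyte percentage and neutrophil count are printed as mean ± SD and
    are sampled as normals truncated at the positivity floor, while CRP and
    eosinophil count remain lognormal.
    """
    specs = {s.name: s for s in load_catalogue(cohort)}
    rng = np.random.default_rng(seed)
    frames = []
    for group, n in (("pso", n_pso), ("psa", n_psa)):
        data = {}
        for name in PSAII_COMPONENTS:
            spec = specs[name]
            p = spec.params[group]
            if spec.family == "lognormal":
                mu, sigma = fit_lognormal_from_quartiles(p["median"], p["q1"], p["q3"])
                data[name] = rng.lognormal(mu, sigma, n)
            else:
                a = (spec.floor - p["mean"]) / p["sd"]
                data[name] = stats.truncnorm.rvs(
                    a, np.inf, loc=p["mean"], scale=p["sd"], size=n, random_state=rng
                )
        df = pd.DataFrame(data)
        df.insert(0, "label", int(group == "psa"))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
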