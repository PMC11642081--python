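"""Synthetic periodontitis-cohort generator.

Emulates the statistical structure the downstream analyses assume: a
three-class mixture of patients —

* class 0 ("none"): no systemic disease;
* class 1: a respiratory/allergy-dominated comorbidity profile
  (allergic rhinitis, allergy, asthma, lung disease, hypothyroidism);
* class 2: a cardiometabolic profile (hypertension, diabetes mellitus,
  cardiac arrhythmia, myocardial infarction, ...).

Within a class, disease flags are independent Bernoulli draws and
demographic/periodontal variables are drawn from class-conditional
(truncated) normals or Bernoullis.  The default specification is calibrated
so that the drawn cohort reproduces the published summary tables of a
3171-patient referral-practice cohort: class weights 52.9% / 21.6% / 25.5%
(i.e. 47.1% comorbid split 45.8 / 54.2), per-class disease prevalences
matching the per-cluster prevalence table, and demographics matching the
per-cluster characteristics table.

Comorbid classes are rejection-sampled to carry >=1 disease.  Because
conditioning on >=1 inflates marginal rates, ``generate`` first deflates
each comorbid class's Bernoulli vector by the scalar s solving
``s = 1 - prod(1 - s * p)`` so that the conditional-on->=1 prevalence of
every disease equals the target rate exactly in expectation.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .cohort import Cohort, DiseaseCodebook, load_codebook, N_DISEASES

__all__ = ["SyntheticSpec", "default_spec", "generate", "perturb"]

CLASS_NAMES = ("none", "respiratory_allergy", "cardiometabolic")

# Per-cluster disease prevalences (%), questionnaire order, from the
# published cluster prevalence table (cluster 1 n=684, cluster 2 n=811).
_CLASS1_PCT = np.array([
    0.1, 0.0, 0.0, 0.3, 0.0, 1.5, 0.0, 1.2, 0.3, 0.0, 0.0, 15.1, 9.5,
    47.5, 47.8, 0.4, 0.4, 13.9, 0.0, 0.1, 0.0, 0.4, 0.0, 0.1, 0.1, 0.1,
])
_CLASS2_PCT = np.array([
    5.9, 8.5, 7.3, 7.4, 1.4, 13.8, 5.8, 12.7, 43.6, 6.8, 2.6, 4.9, 5.8,
    12.0, 23.3, 13.7, 4.2, 3.3, 1.5, 1.8, 3.1, 4.3, 1.8, 2.0, 2.5, 0.5,
])


@dataclass
class ClassDemographics:
    """Class-conditional distributions for demographics and periodontal metrics.

    Continuous variables are (truncated) normal, given as (mean, sd);
    binary variables as a single probability.  PISA is in mm^2.
    """

    age: tuple[float, float]
    female_p: float
    sep: tuple[float, float]          # truncated to [-1, 1]
    smoking_p: float
    n_pockets_ge6: tuple[float, float]   # truncated at 0, rounded
    bop_pct: tuple[float, float]         # truncated to [0, 100]
    n_teeth: tuple[float, float]         # truncated to [0, 32], rounded
    pisa_mm2: tuple[float, float]        # truncated at 0


@dataclass
class SyntheticSpec:
    """Full specification of the synthetic cohort mixture."""

    n: int
    mix: np.ndarray                       # (3,) class probabilities
    disease_probs: np.ndarray             # (3, 26) Bernoulli rates per class
    demo: dict[str, ClassDemographics]    # keyed by CLASS_NAMES
    seed: int = 0
    missing_sep_p: float = 0.009          # small SEP missingness, as observed
    codebook: DiseaseCodebook = field(default_factory=load_codebook)

    def validate(self) -> None:
        mix = np.asarray(self.mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or (mix > 1).any():
            raise ValueError("mix must be 3 probabilities in [0, 1]")
        if abs(mix.sum() - 1.0) > 1e-12:
            raise ValueError("mix must sum to 1")
        probs = np.asarray(self.disease_probs, dtype=float)
        if probs.shape != (3, N_DISEASES):
            raise ValueError(f"disease_probs must be 3 x {N_DISEASES}")
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("disease probabilities must lie in [0, 1]")
        if probs[0].any():
            raise ValueError('class "none" must have all-zero disease rates')
        if not 0 <= self.missing_sep_p <= 1:
            raise ValueError("missing_sep_p must lie in [0, 1]")
        if set(self.demo) != set(CLASS_NAMES):
            raise ValueError(f"demo must be keyed by {CLASS_NAMES}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def default_spec(n: int = 3171, seed: int = 0) -> SyntheticSpec:
    """Specification calibrated to the published cohort tables.

    Mixture weights: 52.9% disease-free; the 47.1% comorbid remainder split
    45.8 / 54.2 between the respiratory/allergy and cardiometabolic classes.
    Disease rates are the per-cluster prevalence-table percentages;
    demographics the per-column characteristics-table means/SDs.
    """
    p_comorbid = 0.471
    mix = np.array([1 - p_comorbid, p_comorbid * 0.458, p_comorbid * 0.542])
    probs = np.vstack([np.zeros(N_DISEASES), _CLASS1_PCT / 100, _CLASS2_PCT / 100])
    demo = {
        # "No comorbidity" column
        "none": ClassDemographics(
            age=(51.3, 12.3), female_p=0.507, sep=(0.07, 0.20), smoking_p=0.260,
            n_pockets_ge6=(20.9, 21.9), bop_pct=(51.5, 25.8),
            n_teeth=(26.0, 3.4), pisa_mm2=(1360.0, 880.0),
        ),
        # Cluster 1 column
        "respiratory_allergy": ClassDemographics(
            age=(51.7, 12.4), female_p=0.680, sep=(0.08, 0.18), smoking_p=0.221,
            n_pockets_ge6=(18.1, 19.8), bop_pct=(48.9, 25.9),
            n_teeth=(25.9, 3.5), pisa_mm2=(1270.0, 850.0),
        ),
        # Cluster 2 column
        "cardiometabolic": ClassDemographics(
            age=(57.4, 11.8), female_p=0.567, sep=(0.05, 0.19), smoking_p=0.252,
            n_pockets_ge6=(21.1, 21.6), bop_pct=(53.6, 26.0),
            n_teeth=(24.9, 3.8), pisa_mm2=(1370.0, 860.0),
        ),
    }
    spec = SyntheticSpec(n=n, mix=mix, disease_probs=probs, demo=demo, seed=seed)
    spec.validate()
    return spec


def conditional_calibration(p: np.ndarray) -> np.ndarray:
    """Deflate a Bernoulli rate vector for conditioning on >=1 success.

    Returns q = s * p with s the fixed point of s = 1 - prod(1 - s p), so
    that under independent Bernoulli(q) draws conditioned on at least one
    success, P(flag_d = 1 | >=1) = q_d / (1 - prod(1 - q)) = p_d exactly.
    """
    p = np.asarray(p, dtype=float)
    if not p.any():
        return p.copy()
    # feasibility: conditional on >=1 success the expected count is >= 1, so
    # target rates summing to <= 1 cannot arise from any independent draw
    # (the fixed-point map then only has the degenerate root s = 0)
    if p.sum() <= 1.0:
        raise ValueError(
            "target conditional rates infeasible: per-class disease rates must "
            f"sum to > 1 to be conditional-on->=1 prevalences (got {p.sum():.3f})")
    s = 1.0
    for _ in range(500):
        s_new = 1.0 - np.prod(1.0 - s * p)
        if abs(s_new - s) < 1e-15:
            break
        s = s_new
    return s * p


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    if sd <= 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _draw_flags(rng: np.random.Generator, q: np.ndarray, size: int,
                require_one: bool) -> np.ndarray:
    flags = (rng.random((size, q.size)) < q).astype(np.int8)
    if require_one:
        bad = np.flatnonzero(flags.sum(axis=1) == 0)
        while bad.size:
            flags[bad] = (rng.random((bad.size, q.size)) < q).astype(np.int8)
            bad = bad[flags[bad].sum(axis=1) == 0]
    return flags


def generate(spec: SyntheticSpec) -> tuple[Cohort, np.ndarray]:
    """Draw a cohort from the mixture; returns (cohort, true class labels).

    Deterministic given ``spec.seed``: one root generator drives the class
    draw, the flag draws and every demographic draw in a fixed order.
    Labels are integers 0/1/2 indexing ``CLASS_NAMES``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    labels = rng.choice(3, size=n, p=np.asarray(spec.mix, dtype=float))

    flags = np.zeros((n, N_DISEASES), dtype=np.int8)
    cols = {
        "age": np.empty(n), "sex": np.empty(n, dtype=object),
        "sep": np.empty(n), "smoking": np.empty(n, dtype=int),
        "n_teeth": np.empty(n, dtype=int), "n_pockets_ge6": np.empty(n, dtype=int),
        "bop_pct": np.empty(n), "pisa_mm2": np.empty(n),
    }
    for c, name in enumerate(CLASS_NAMES):
        idx = np.flatnonzero(labels == c)
        m = idx.size
        if m == 0:
            continue
        if c > 0:
            q = conditional_calibration(np.asarray(spec.disease_probs[c]))
            flags[idx] = _draw_flags(rng, q, m, require_one=True)
        d = spec.demo[name]
        cols["age"][idx] = np.maximum(18.0, rng.normal(d.age[0], d.age[1], m))
        cols["sex"][idx] = np.where(rng.random(m) < d.female_p, "female", "male")
        cols["sep"][idx] = _trunc_normal(rng, d.sep[0], d.sep[1], -1.0, 1.0, m)
        cols["smoking"][idx] = (rng.random(m) < d.smoking_p).astype(int)
        cols["n_pockets_ge6"][idx] = np.rint(
            _trunc_normal(rng, *d.n_pockets_ge6, 0.0, np.inf, m)).astype(int)
        cols["bop_pct"][idx] = _trunc_normal(rng, *d.bop_pct, 0.0, 100.0, m)
        cols["n_teeth"][idx] = np.rint(
            _trunc_normal(rng, *d.n_teeth, 0.0, 32.0, m)).astype(int)
        cols["pisa_mm2"][idx] = _trunc_normal(rng, *d.pisa_mm2, 0.0, np.inf, m)

    if spec.missing_sep_p > 0:
        cols["sep"][rng.random(n) < spec.missing_sep_p] = np.nan

    import pandas as pd

    frame = pd.DataFrame({"patient_id": [f"P{i:06d}" for i in range(n)], **cols})
    for j, disease in enumerate(spec.codebook.diseases):
        frame[disease] = flags[:, j]
    return Cohort(frame, spec.codebook), labels


def perturb(spec: SyntheticSpec, overrides: dict) -> SyntheticSpec:
    """Return a modified copy of ``spec``; the original is untouched.

    Keys are dotted field paths, e.g. ``"seed"``, ``"mix"``,
    ``"disease_probs[1]"`` is not supported — use tuple keys
    ``("disease_probs", class_index, disease_index)`` or replace the whole
    array.  Demographic fields address ``"demo.<class>.<field>"``.
    Unknown keys and invalid values raise ValueError.
    """
    out = copy.deepcopy(spec)
    for key, value in overrides.items():
        if isinstance(key, tuple):
            name, *idx = key
            if name != "disease_probs" or len(idx) not in (1, 2):
                raise ValueError(f"unknown override key: {key!r}")
            arr = np.array(out.disease_probs, dtype=float)
            arr[tuple(idx)] = value
            out.disease_probs = arr
            continue
        parts = key.split(".")
        if parts[0] == "demo":
            if len(parts) != 3 or parts[1] not in out.demo:
                raise ValueError(f"unknown override key: {key!r}")
            demo = out.demo[parts[1]]
            if not hasattr(demo, parts[2]):
                raise ValueError(f"unknown override key: {key!r}")
            setattr(demo, parts[2], value)
        elif len(parts) == 1 and hasattr(out, key) and key != "codebook":
            if key in ("mix", "disease_probs"):
                value = np.asarray(value, dtype=float)
            setattr(out, key, value)
        else:
            raise ValueError(f"unknown override key: {key!r}")
    out.validate()
    return out
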