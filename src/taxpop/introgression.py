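"""Generation-recursive dynamics of introgression at a paternally
inherited haploid (chloroplast) locus versus a biparental nuclear locus
in a dioecious plant, under pollen-only or seed-only gene flow.

The model tracks the exotic-gene frequency at the cp locus among males
(``x_M``) and females (``x_F``) and at the nuclear locus (``y_M``,
``y_F``) through discrete non-overlapping generations.  Chloroplasts are
transmitted only by fathers; a seed immigrant carries exotic states at
both loci; a pollen immigrant sires offspring whose cp is fully exotic
but whose nuclear genome is only half exotic.  Sex-ratio-adjusting
mechanisms enter through ``phi_e``, the probability that an
exotic-origin recruit is female (``phi_l`` for local-origin recruits).
The population-level introgression level at each locus is the
equal-weight average of the two sex pools.

An individual-based forward simulator (:func:`forward_oracle`) provides
an independent finite-population check of the recursions, and
:func:`calibrate` fits the flow rate and ``phi_e`` to observed cp and
nuclear introgression levels.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class IntrogressionParams:
    """Parameters of the introgression recursion.

    mode
        ``"pollen"``: a fraction ``rate`` of seeds each generation are
        sired by exotic pollen.  ``"seed"``: a fraction ``rate`` of
        recruits are exotic seeds.
    rate
        Gene-flow rate per generation (p or s above), in [0, 1].
    phi_e, phi_l
        Probability that an exotic-origin / local-origin recruit is
        female.  Defaults 0.5 (even sex ratios).
    generations
        Number of generations to iterate (25-year generations for any
        calendar conversion).
    """

    mode: str
    rate: float
    phi_e: float = 0.5
    phi_l: float = 0.5
    generations: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("pollen", "seed"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name in ("rate", "phi_e", "phi_l"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class IntrogressionState:
    x_M: float = 0.0
    x_F: float = 0.0
    y_M: float = 0.0
    y_F: float = 0.0
    generation: int = 0

    @property
    def L_cp(self) -> float:
        return 0.5 * (self.x_M + self.x_F)

    @property
    def L_nuc(self) -> float:
        return 0.5 * (self.y_M + self.y_F)


def step(state: IntrogressionState, params: IntrogressionParams) -> IntrogressionState:
    """Advance the recursion by one generation.

    Pollen mode: every recruit has a local mother; the father is exotic
    pollen with probability p, otherwise drawn from the local male pool.
    Offspring cp comes from the father (exotic pollen => fully exotic);
    the nuclear frequency is the mean of the maternal pool and the
    (exotic-or-local) paternal contribution.  Both sexes of recruits are
    identical, so the sex-ratio parameters play no role.

    Seed mode: recruits are a mixture of exotic seeds (both loci exotic)
    and local offspring (cp from the local male pool, nuclear the mean of
    the two local pools); exotic recruits are female with probability
    phi_e, local ones with probability phi_l, and each sex pool is the
    mixture conditioned on that sex.
    """
    r = params.rate
    if params.mode == "pollen":
        x_new = r + (1.0 - r) * state.x_M
        y_bar_father = r * 1.0 + (1.0 - r) * state.y_M
        y_new = 0.5 * (state.y_F + y_bar_father)
        return IntrogressionState(x_M=x_new, x_F=x_new, y_M=y_new, y_F=y_new,
                                  generation=state.generation + 1)

    male_mass = r * (1.0 - params.phi_e) + (1.0 - r) * (1.0 - params.phi_l)
    female_mass = r * params.phi_e + (1.0 - r) * params.phi_l
    if male_mass == 0.0:
        raise ValueError("no males recruited (phi_e and phi_l both 1 with s>0)")
    if female_mass == 0.0:
        raise ValueError("no females recruited (phi_e and phi_l both 0 with s>0)")
    y_local = 0.5 * (state.y_M + state.y_F)
    x_M = (r * (1.0 - params.phi_e) * 1.0
           + (1.0 - r) * (1.0 - params.phi_l) * state.x_M) / male_mass
    x_F = (r * params.phi_e * 1.0
           + (1.0 - r) * params.phi_l * state.x_M) / female_mass
    y_M = (r * (1.0 - params.phi_e) * 1.0
           + (1.0 - r) * (1.0 - params.phi_l) * y_local) / male_mass
    y_F = (r * params.phi_e * 1.0
           + (1.0 - r) * params.phi_l * y_local) / female_mass
    return IntrogressionState(x_M=x_M, x_F=x_F, y_M=y_M, y_F=y_F,
                              generation=state.generation + 1)


def trajectory(params: IntrogressionParams) -> pd.DataFrame:
    """Iterate :func:`step` from the all-zero state.

    Returns one row per generation 0..T with the sex-pool frequencies and
    the sex-averaged levels ``L_cp`` and ``L_nuc``.
    """
    if params.generations < 1:
        raise ValueError("need at least one generation")
    state = IntrogressionState()
    rows = [state]
    for _ in range(params.generations):
        state = step(state, params)
        rows.append(state)
    return pd.DataFrame({
        "generation": [s.generation for s in rows],
        "x_M": [s.x_M for s in rows],
        "x_F": [s.x_F for s in rows],
        "y_M": [s.y_M for s in rows],
        "y_F": [s.y_F for s in rows],
        "L_cp": [s.L_cp for s in rows],
        "L_nuc": [s.L_nuc for s in rows],
    })


# --------------------------------------------------------------------------
# individual-based forward oracle


@dataclass
class OracleResult:
    L_cp: float
    L_nuc: float
    se_cp: float
    se_nuc: float
    n_replicates: int
    n_discarded: int = 0


def forward_oracle(params: IntrogressionParams, N: int, T: int | None = None,
                   seed: int | None = None, replicates: int = 50) -> OracleResult:
    """Individual-based dioecious simulation of the same process.

    Each generation ``N`` recruits are formed: in seed mode each recruit
    is an exotic seed with probability ``rate`` (cp exotic, both nuclear
    alleles exotic, female with probability phi_e), otherwise the child
    of a random local mother and father; in pollen mode every recruit has
    a local mother and an exotic-pollen father with probability ``rate``.
    Chloroplasts follow the father; each parent passes one nuclear
    allele.  The recursion of :func:`step` is the infinite-N limit of
    this process.  Replicates in which a sex class goes extinct are
    discarded with a warning.
    """
    if N < 50:
        raise ValueError("use at least 50 individuals")
    T = params.generations if T is None else T
    rng = np.random.default_rng(seed)
    cps, nucs = [], []
    discarded = 0
    for _ in range(replicates):
        out = _forward_once(params, N, T, rng)
        if out is None:
            discarded += 1
            continue
        cps.append(out[0])
        nucs.append(out[1])
    if discarded:
        _warnings.warn(f"{discarded} replicate(s) discarded after sex-class extinction")
    if not cps:
        raise RuntimeError("all replicates lost a sex class; increase N")
    cps, nucs = np.asarray(cps), np.asarray(nucs)
    k = len(cps)
    return OracleResult(
        L_cp=float(cps.mean()), L_nuc=float(nucs.mean()),
        se_cp=float(cps.std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
        se_nuc=float(nucs.std(ddof=1) / np.sqrt(k)) if k > 1 else np.nan,
        n_replicates=k, n_discarded=discarded)


def _forward_once(params, N, T, rng):
    female = rng.random(N) < 0.5
    cp = np.zeros(N, dtype=np.int8)
    al1 = np.zeros(N, dtype=np.int8)
    al2 = np.zeros(N, dtype=np.int8)
    r = params.rate
    for _ in range(T):
        males = np.flatnonzero(~female)
        females = np.flatnonzero(female)
        if len(males) == 0 or len(females) == 0:
            return None
        mothers = rng.choice(females, size=N)
        fathers = rng.choice(males, size=N)
        m_allele = np.where(rng.random(N) < 0.5, al1[mothers], al2[mothers])
        f_allele = np.where(rng.random(N) < 0.5, al1[fathers], al2[fathers])
        if params.mode == "pollen":
            exo_father = rng.random(N) < r
            new_cp = np.where(exo_father, 1, cp[fathers])
            new_al1 = m_allele
            new_al2 = np.where(exo_father, 1, f_allele)
            new_female = rng.random(N) < params.phi_l
        else:
            exo_seed = rng.random(N) < r
            new_cp = np.where(exo_seed, 1, cp[fathers])
            new_al1 = np.where(exo_seed, 1, m_allele)
            new_al2 = np.where(exo_seed, 1, f_allele)
            phi = np.where(exo_seed, params.phi_e, params.phi_l)
            new_female = rng.random(N) < phi
        cp, al1, al2, female = new_cp, new_al1, new_al2, new_female
    males = ~female
    if males.sum() == 0 or female.sum() == 0:
        return None
    L_cp = 0.5 * (cp[males].mean() + cp[female].mean())
    nuc = 0.5 * (al1 + al2)
    L_nuc = 0.5 * (nuc[males].mean() + nuc[female].mean())
    return float(L_cp), float(L_nuc)


# --------------------------------------------------------------------------
# calibration to observed levels


@dataclass
class ObservedLevels:
    L_cp: float
    L_nuc: float

    def __post_init__(self) -> None:
        for v in (self.L_cp, self.L_nuc):
            if not 0.0 <= v <= 1.0:
                raise ValueError("observed levels must lie in [0, 1]")


@dataclass
class CalibrationResult:
    """Best-fit parameters and the full objective surface."""

    mode: str
    feasible: bool
    rate: float | None
    phi_e: float | None
    generations: int
    objective: float | None
    surface: pd.DataFrame
    message: str = ""

    def summary(self) -> str:
        if not self.feasible:
            return f"mode {self.mode!r}: {self.message}"
        return (f"mode {self.mode!r}: rate={self.rate:.4g}, "
                f"phi_e={self.phi_e:.3g}, T={self.generations}, "
                f"sse={self.objective:.3g}")


def calibrate(observed: ObservedLevels, mode: str, generations: int,
              rate_grid=None, phi_grid=None, phi_l: float = 0.5) -> CalibrationResult:
    """Grid least-squares fit of (rate, phi_e) to observed levels.

    Minimises the squared error between the trajectory endpoint
    ``(L_cp, L_nuc)`` and the observation.  Under pollen-only flow the
    model cannot produce ``L_nuc > L_cp`` (cp introgression always runs
    ahead), so such targets return an explicit infeasibility result
    rather than a silent best fit.
    """
    if not (0.0 < observed.L_cp < 1.0) or not (0.0 < observed.L_nuc < 1.0):
        raise ValueError("observed levels must lie strictly in (0, 1)")
    if mode == "pollen" and observed.L_nuc > observed.L_cp:
        return CalibrationResult(
            mode=mode, feasible=False, rate=None, phi_e=None,
            generations=generations, objective=None,
            surface=pd.DataFrame(columns=["rate", "phi_e", "sse"]),
            message=("pollen-only flow cannot produce a nuclear "
                     "introgression level above the chloroplast level"))
    if rate_grid is None:
        rate_grid = np.geomspace(1e-4, 0.5, 60)
    if phi_grid is None:
        phi_grid = [0.5] if mode == "pollen" else np.linspace(0.5, 0.99, 25)
    rows = []
    for rate in rate_grid:
        for phi_e in phi_grid:
            params = IntrogressionParams(mode=mode, rate=float(rate),
                                         phi_e=float(phi_e), phi_l=phi_l,
                                         generations=generations)
            end = trajectory(params).iloc[-1]
            sse = ((end["L_cp"] - observed.L_cp) ** 2
                   + (end["L_nuc"] - observed.L_nuc) ** 2)
            rows.append((float(rate), float(phi_e), float(end["L_cp"]),
                         float(end["L_nuc"]), float(sse)))
    surface = pd.DataFrame(rows, columns=["rate", "phi_e", "L_cp", "L_nuc", "sse"])
    best = surface.loc[surface["sse"].idxmin()]
    return CalibrationResult(
        mode=mode, feasible=True, rate=float(best["rate"]),
        phi_e=float(best["phi_e"]), generations=generations,
        objective=float(best["sse"]), surface=surface)
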