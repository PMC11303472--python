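"""Virtual crossover studies with the trial's design and covariate structure.

The generator emulates a 2-period, 2-sequence single-dose (600 mg) crossover
in healthy volunteers: 24 subjects (11 male / 13 female by default), two
occasions separated by a washout long enough for complete elimination (no
carryover), 19 post-dose samples plus a predose sample per occasion, and an
assay LLOQ of 0.1 mg/L.

Covariates are drawn per sex from truncated normals calibrated to the
reported demographics (mean = median, SD = range/4, truncated to the printed
range); (BW, BH) pairs are redrawn until BMI falls in the 18.5-30 kg/m^2
eligibility window, which keeps BMI = BW/BH^2 exact.  FFM and BSA are derived,
never sampled, so the sex-disjoint FFM ranges emerge from the FFM model
itself.

Draw order under a fixed seed (documented determinism): covariates subject by
subject, then all eta, then all kappa, then residual noise subject-major,
occasion-minor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .covariates import weighted_mean
from .dataio import NOMINAL_TIMES, EventTable, SubjectCovariates
from .popmodel import PARAM_ORDER, PopulationModel, draw_effects

__all__ = ["DesignSpec", "sample_covariates", "simulate_study", "SimulatedStudy"]

#: demographics as (median, low, high) per sex: BW kg, BH m, age years
COVARIATE_RANGES = {
    "female": {"bw": (63.8, 48.5, 73.1), "bh": (1.65, 1.55, 1.76),
               "age": (37.0, 21.0, 58.0)},
    "male": {"bw": (82.9, 57.8, 91.0), "bh": (1.81, 1.63, 1.89),
             "age": (43.0, 22.0, 64.0)},
}

BMI_ELIGIBILITY = (18.5, 30.0)


@dataclass
class DesignSpec:
    """Study design: arm sizes, dose, sampling grid, occasions, LLOQ."""

    n_male: int = 11
    n_female: int = 13
    dose_mg: float = 600.0
    sampling_times: tuple[float, ...] = NOMINAL_TIMES
    include_predose: bool = True
    n_occasions: int = 2
    lloq: float = 0.1
    ranges: dict = field(default_factory=lambda: COVARIATE_RANGES)
    bmi_range: tuple[float, float] = BMI_ELIGIBILITY

    def __post_init__(self):
        if self.n_male < 0 or self.n_female < 0 or self.n_male + self.n_female == 0:
            raise ValueError("need at least one subject")
        if self.lloq <= 0:
            raise ValueError("lloq must be positive")

    @property
    def n_subjects(self) -> int:
        return self.n_male + self.n_female


def _trunc_normal(rng: np.random.Generator, median: float, lo: float,
                  hi: float) -> float:
    sd = (hi - lo) / 4.0
    for _ in range(10_000):
        x = median + sd * rng.standard_normal()
        if lo <= x <= hi:
            return x
    return median  # pragma: no cover - unreachable at the shipped ranges


def sample_covariates(spec: DesignSpec,
                      rng: np.random.Generator) -> list[SubjectCovariates]:
    """Draw demographics for every subject; deterministic under a fixed rng."""
    sexes = ["male"] * spec.n_male + ["female"] * spec.n_female
    out = []
    for idx, sex in enumerate(sexes):
        r = spec.ranges[sex]
        for _ in range(10_000):
            bw = _trunc_normal(rng, *r["bw"])
            bh = _trunc_normal(rng, *r["bh"])
            if spec.bmi_range[0] <= bw / bh**2 <= spec.bmi_range[1]:
                break
        age = _trunc_normal(rng, *r["age"])
        # alternating randomized sequence: test-reference / reference-test
        prep = ("test", "reference") if idx % 2 == 0 else ("reference", "test")
        out.append(SubjectCovariates(sex=sex, bw=bw, bh=bh, age=age,
                                     preparation=prep[: spec.n_occasions]
                                     or ("test",)))
    return out


@dataclass
class SimulatedStudy:
    """A generated study: the event table plus the generating truth."""

    table: EventTable
    truth: pd.DataFrame          # individual parameters and effects
    model: PopulationModel       # generating model with resolved references


def simulate_study(model: PopulationModel, spec: DesignSpec,
                   rng: np.random.Generator,
                   covariates: list[SubjectCovariates] | None = None
                   ) -> SimulatedStudy:
    """Simulate a complete study under the population model.

    Any unresolved covariate normalization references are set to the realized
    sample's observation-weighted means, so that a subsequent fit of the same
    dataset uses the identical normalization.
    """
    covs = covariates if covariates is not None else sample_covariates(spec, rng)
    ns = len(covs)
    nocc = spec.n_occasions
    times = np.asarray(
        ((0.0,) if spec.include_predose else ()) + tuple(spec.sampling_times),
        dtype=float)
    n_per_occ = len(times)

    if model.has_unresolved_references():
        refs = {}
        w = [float(n_per_occ * nocc)] * ns
        for name in ("BW", "BH", "age", "BMI", "BSA", "FFM"):
            refs[name] = weighted_mean([c.as_dict()[name] for c in covs], w)
        model = model.resolve_references(refs)

    eta, kappa = draw_effects(model, ns, nocc, rng)
    ltheta = np.log([model.theta[p] for p in PARAM_ORDER])
    lkm = np.log(model.theta["Km"])
    flags = model.variant.flags

    rows = []
    truth_rows = []
    for i, cov in enumerate(covs):
        sid = f"S{i + 1:02d}"
        for o in range(nocc):
            cd = cov.as_dict(o + 1)
            offs = model.log_offsets(cd)
            lp = ltheta + offs + eta[i] + kappa[i, o]
            conc = np.empty(n_per_occ)
            K._occ_conc(lp, lkm, spec.dose_mg, times, n_per_occ, *flags, conc)
            g = np.maximum(model.error_a + model.error_b * conc, 1e-12)
            y = conc + g * rng.standard_normal(n_per_occ)
            cens = (y < spec.lloq).astype(int)
            dv = np.where(cens == 1, spec.lloq, y)

            base = {"ID": sid, "OCC": o + 1, "SEX": cov.sex, "BW": cov.bw,
                    "BH": cov.bh, "AGE": cov.age, "PREP": cd["preparation"]}
            rows.append({**base, "TIME": 0.0, "EVID": 1, "AMT": spec.dose_mg,
                         "DV": np.nan, "CENS": 0})
            for jt in range(n_per_occ):
                rows.append({**base, "TIME": times[jt], "EVID": 0, "AMT": 0.0,
                             "DV": dv[jt], "CENS": int(cens[jt])})
            truth_rows.append({
                "ID": sid, "OCC": o + 1,
                **{p: float(np.exp(lp[j])) for j, p in enumerate(PARAM_ORDER)},
                "Km": model.theta["Km"],
                **{f"eta_{p}": eta[i, j] for j, p in enumerate(PARAM_ORDER)},
                **{f"kappa_{p}": kappa[i, o, j]
                   for j, p in enumerate(PARAM_ORDER)},
            })

    df = pd.DataFrame(rows)
    table = EventTable(df, lloq=spec.lloq)
    return SimulatedStudy(table=table, truth=pd.DataFrame(truth_rows),
                          model=model)
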