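"""Seeded synthetic PET/CT survival cohorts.

Emulates the statistical structure of a lung-SBRT imaging cohort: each case
carries one or more tumor-like bright blobs rendered on two co-registered
modalities (a high-resolution CT-like patch and a coarser PET-like patch),
a clinical table (age, gender, SUVmax, radiation dose) and four
time-to-event outcomes (OS, RFS, DC observed per case; LC per tumor).

The image features that drive outcome are explicit: a latent log-hazard
``z(area) + z(mean ROI intensity) + z(texture roughness)``, standardized
within the cohort, enters an exponential proportional-hazards model together
with standardized clinical covariates. Censoring is the minimum of an
independent exponential and an administrative horizon. Every draw flows from
a single ``numpy`` Generator, so one seed reproduces the cohort bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

OUTCOMES = ("OS", "RFS", "DC", "LC")

__all__ = [
    "OUTCOMES",
    "CohortSpec",
    "SurvivalRecord",
    "Tumor",
    "Clinical",
    "TumorCase",
    "generate_cohort",
    "select_index_tumor",
    "split_train_test",
    "records_to_frame",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings.

    Defaults emulate the target population: ~132 early-stage lung cancer
    cases, occasionally multifocal, followed for a few years with a median
    observed time in the vicinity of 27 months. Rates are per month.
    """

    n_cases: int = 132
    tumors_per_case_range: tuple[int, int] = (1, 2)
    canvas_ct: int = 80
    canvas_pet: int = 28
    beta_image: float = 0.7
    beta_clinical: tuple[float, float, float, float] = (0.25, 0.10, 0.30, -0.10)
    baseline_rate: float = 0.015
    censor_rate: float = 0.012
    admin_horizon: float = 60.0
    seed: int = 0

    def validate(self):
        if self.n_cases < 2:
            raise ValueError("n_cases must be at least 2")
        if self.canvas_ct <= 0 or self.canvas_pet <= 0:
            raise ValueError("canvas sides must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        if self.admin_horizon <= 0:
            raise ValueError("admin_horizon must be positive")
        lo, hi = self.tumors_per_case_range
        if not (1 <= lo <= hi):
            raise ValueError("tumors_per_case_range must be a range within [1, inf)")


@dataclass
class SurvivalRecord:
    """One subject's follow-up for one outcome (time in months)."""

    case_id: str
    time: float
    event: int
    outcome: str
    tumor_index: int | None = None  # set for the per-tumor LC outcome

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("time must be strictly positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")


@dataclass
class Tumor:
    ct: np.ndarray        # (canvas_ct, canvas_ct, 3) float32, slices below/middle/above
    pet: np.ndarray       # (canvas_pet, canvas_pet, 3) float32
    ct_mask: np.ndarray   # (canvas_ct, canvas_ct) bool, middle-slice ROI
    pet_mask: np.ndarray  # (canvas_pet, canvas_pet) bool
    suv: float
    roughness: float      # texture noise scale (hidden generator parameter)
    latent_risk: float = 0.0


@dataclass
class Clinical:
    age: float
    gender: int
    suv_max: float
    dose: float

    def as_array(self):
        return np.array([self.age, self.gender, self.suv_max, self.dose])


@dataclass
class TumorCase:
    case_id: str
    tumors: list[Tumor]
    clinical: Clinical
    latent_risk: float = 0.0  # hidden ground truth of the index tumor


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _ellipse_mask(side, cy, cx, a, b, theta):
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _render_slice(side, cy, cx, a, b, theta, mu, roughness, rng):
    """Bright elliptical blob with radial falloff plus correlated noise."""
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    r2 = (u / a) ** 2 + (v / b) ** 2
    mask = r2 <= 1.0
    base = mu * (1.0 - 0.35 * r2)
    noise = gaussian_filter(rng.standard_normal((side, side)), sigma=1.0)
    img = np.where(mask, np.clip(base + roughness * noise, 0.05, 1.0), 0.0)
    return img.astype(np.float32), mask


def _make_tumor(spec: CohortSpec, rng: np.random.Generator) -> Tumor:
    side_ct, side_pet = spec.canvas_ct, spec.canvas_pet
    # CT semi-axes sized so the tumor (and its 20-px multiscale margin) fits
    a = rng.uniform(0.05, 0.28) * side_ct
    b = a * rng.uniform(0.6, 1.0)
    theta = rng.uniform(0.0, np.pi)
    mu = rng.uniform(0.35, 0.85)
    roughness = rng.uniform(0.02, 0.25)
    cy = side_ct / 2 + rng.uniform(-2, 2)
    cx = side_ct / 2 + rng.uniform(-2, 2)

    slices, masks = [], []
    for scale in (rng.uniform(0.75, 0.95), 1.0, rng.uniform(0.75, 0.95)):
        img, m = _render_slice(side_ct, cy, cx, a * scale, b * scale, theta,
                               mu, roughness, rng)
        slices.append(img)
        masks.append(m)
    ct = np.stack(slices, axis=-1)
    ct_mask = masks[1]

    area_frac = ct_mask.mean()
    suv = float(np.clip(1.5 + 18.0 * mu * area_frac ** 0.25
                        + rng.normal(0.0, 0.6), 0.3, None))

    # co-registered PET: same geometry scaled to the PET grid, uptake tied to SUV
    s = side_pet / side_ct
    mu_pet = float(np.clip(0.2 + suv / 20.0, 0.2, 0.95))
    pslices, pmasks = [], []
    for scale in (0.85, 1.0, 0.85):
        img, m = _render_slice(side_pet, cy * s, cx * s,
                               max(a * s * scale, 1.2), max(b * s * scale, 1.2),
                               theta, mu_pet, roughness, rng)
        pslices.append(img)
        pmasks.append(m)
    pet = np.stack(pslices, axis=-1)
    return Tumor(ct=ct, pet=pet, ct_mask=ct_mask, pet_mask=pmasks[1],
                 suv=suv, roughness=roughness)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _zscore(x):
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def _draw_time(rate, rng):
    return float(rng.exponential(1.0 / rate))


def generate_cohort(spec: CohortSpec):
    """Generate a cohort.

    Returns ``(cases, records)`` where ``records`` maps each outcome name to
    its list of :class:`SurvivalRecord` (one per case for OS/RFS/DC, one per
    tumor for LC).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.tumors_per_case_range

    cases: list[TumorCase] = []
    for i in range(spec.n_cases):
        n_t = int(rng.integers(lo, hi + 1))
        tumors = [_make_tumor(spec, rng) for _ in range(n_t)]
        age = float(np.clip(rng.normal(74.65, 8.5), 52, 92))
        gender = int(rng.integers(0, 2))
        dose = float(np.clip(rng.normal(120.0, 15.0), 80, 160))
        suv_max = max(t.suv for t in tumors)
        cases.append(TumorCase(
            case_id=f"case{i:04d}", tumors=tumors,
            clinical=Clinical(age=age, gender=gender, suv_max=suv_max, dose=dose)))

    # latent risk per tumor: standardized area + mean ROI intensity + roughness
    all_tumors = [t for c in cases for t in c.tumors]
    areas = _zscore([t.ct_mask.sum() for t in all_tumors])
    mus = _zscore([float(t.ct[..., 1][t.ct_mask].mean()) for t in all_tumors])
    roughs = _zscore([t.roughness for t in all_tumors])
    raw = areas + mus + roughs
    latent = raw / raw.std() if raw.std() > 0 else raw
    for t, z in zip(all_tumors, latent):
        t.latent_risk = float(z)
    for c in cases:
        c.latent_risk = select_index_tumor(c).latent_risk

    # standardized clinical covariates enter the hazard
    clin = np.array([c.clinical.as_array() for c in cases])
    zclin = np.column_stack([_zscore(clin[:, j]) for j in range(4)])
    beta_c = np.asarray(spec.beta_clinical, dtype=float)

    records: dict[str, list[SurvivalRecord]] = {o: [] for o in OUTCOMES}
    for idx, case in enumerate(cases):
        clin_term = float(zclin[idx] @ beta_c)
        censor = spec.admin_horizon
        if spec.censor_rate > 0:
            censor = min(censor, _draw_time(spec.censor_rate, rng))
        for outcome in ("OS", "RFS", "DC"):
            rate = spec.baseline_rate * np.exp(
                spec.beta_image * case.latent_risk + clin_term)
            t_star = _draw_time(rate, rng)
            records[outcome].append(SurvivalRecord(
                case_id=case.case_id, time=min(t_star, censor),
                event=int(t_star < censor), outcome=outcome))
        for k, tumor in enumerate(case.tumors):
            rate = spec.baseline_rate * np.exp(
                spec.beta_image * tumor.latent_risk + clin_term)
            t_star = _draw_time(rate, rng)
            records["LC"].append(SurvivalRecord(
                case_id=case.case_id, time=min(t_star, censor),
                event=int(t_star < censor), outcome="LC", tumor_index=k))
    return cases, records


def select_index_tumor(case: TumorCase) -> Tumor:
    """The index tumor: highest SUV, ties broken by lowest tumor index."""
    if not case.tumors:
        raise ValueError("case has no tumors")
    suvs = np.array([t.suv for t in case.tumors])
    return case.tumors[int(np.argmax(suvs))]


def split_train_test(case_ids, fraction, seed):
    """Case-level train/test split.

    ``n_train = round(fraction * n)`` (banker's-free: ties round half up),
    clipped so both sides are nonempty. All tumors of a case stay together
    because the split is over case ids.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    ids = [c.case_id if isinstance(c, TumorCase) else str(c) for c in case_ids]
    if len(set(ids)) != len(ids):
        ids = list(dict.fromkeys(ids))
    n = len(ids)
    if n < 2:
        raise ValueError("need at least two cases to split")
    n_train = int(np.floor(fraction * n + 0.5))
    n_train = min(max(n_train, 1), n - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train = sorted(ids[k] for k in perm[:n_train])
    test = sorted(ids[k] for k in perm[n_train:])
    return train, test


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def records_to_frame(records) -> pd.DataFrame:
    """Flatten a per-outcome record dict into a tidy DataFrame."""
    rows = []
    for outcome, recs in records.items():
        for r in recs:
            rows.append({"case_id": r.case_id, "tumor_index": r.tumor_index,
                         "outcome": outcome, "time": r.time, "event": r.event})
    return pd.DataFrame(rows)


def write_cohort(cases, records, out_dir):
    """Write the cohort: clinical+survival CSV, NPZ image stacks, manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    by_case = {o: {r.case_id: r for r in recs}
               for o, recs in records.items() if o != "LC"}
    lc = {(r.case_id, r.tumor_index): r for r in records.get("LC", [])}
    for case in cases:
        for k, tumor in enumerate(case.tumors):
            row = {"case_id": case.case_id, "tumor_id": k,
                   "age": case.clinical.age, "gender": case.clinical.gender,
                   "suv": tumor.suv, "dose": case.clinical.dose}
            for o in ("OS", "RFS", "DC"):
                rec = by_case.get(o, {}).get(case.case_id)
                if rec is not None:
                    row[f"time_{o}"] = rec.time
                    row[f"event_{o}"] = rec.event
            rec = lc.get((case.case_id, k))
            if rec is not None:
                row["time_LC"] = rec.time
                row["event_LC"] = rec.event
            rows.append(row)
    pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)

    arrays = {}
    manifest = []
    for case in cases:
        for k, tumor in enumerate(case.tumors):
            key = f"{case.case_id}_t{k}"
            arrays[f"{key}_ct"] = tumor.ct
            arrays[f"{key}_pet"] = tumor.pet
            arrays[f"{key}_ct_mask"] = tumor.ct_mask
            arrays[f"{key}_pet_mask"] = tumor.pet_mask
            manifest.append({"case_id": case.case_id, "tumor_id": k,
                             "ct": f"{key}_ct", "pet": f"{key}_pet",
                             "suv": tumor.suv})
    np.savez(out / "images.npz", **arrays)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def export_patch_png(tumor: Tumor, path):
    """Middle CT and PET slices side by side as an 8-bit PNG, for eyeballing."""
    from PIL import Image

    ct = tumor.ct[..., 1]
    pet = tumor.pet[..., 1]
    side = ct.shape[0]
    pet_up = np.kron(pet, np.ones((side // pet.shape[0] + 1,) * 2))[:side, :side]
    panel = np.concatenate([ct, pet_up], axis=1)
    img = (np.clip(panel, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(img).save(path)
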