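"""End-to-end orchestration: synthesize or load a cohort, preprocess both
modalities, train the CT and PET risk branches per outcome, feed risks and
clinical factors to a stepwise Cox model, score the held-out test set, and
optionally run the hand-crafted radiomics arm and the random survival
forest. Reports are plain dicts serialized as JSON with sorted keys, so one
config and seed give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess as prep
from .cohort import (OUTCOMES, CohortSpec, generate_cohort, select_index_tumor,
                     split_train_test)
from .forest import ForestSpec, fit_forest, oob_error, risk_score, vimp
from .nnet import RiskNetSpec, build_risk_net, pretrain_cae, score_risks, train_risk_net
from .radiomics import handcrafted_pipeline
from .survival import concordance_index, kaplan_meier, optimal_cutoff, stepwise_select

CLINICAL_NAMES = ("age", "gender", "SUV", "dose")
DEEP_PREDICTORS = ("CT_risk", "PET_risk") + CLINICAL_NAMES

__all__ = [
    "RunConfig",
    "run_deep",
    "run_handcrafted",
    "run_combined",
    "run_forest",
    "compare_arms",
    "validate_report",
    "REPORT_SCHEMA",
]


@dataclass
class RunConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    outcomes: tuple[str, ...] = OUTCOMES
    mode: str = "deep"                  # deep | handcrafted | both
    channel_mode: str = "slices"        # slices | scales
    train_fraction: float = 0.8
    epochs: int = 150
    learning_rate: float = 1e-3
    init: str = "random"                # random | cae
    cae_epochs: int = 40
    alpha: float = 0.05
    run_rsf: bool = False
    forest: ForestSpec = field(default_factory=lambda: ForestSpec(n_trees=200))
    rsf_horizon: float = 24.0
    seed: int = 0

    def validate(self):
        if not self.outcomes:
            raise ValueError("need at least one outcome")
        bad = set(self.outcomes) - set(OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcomes: {sorted(bad)}")
        if self.mode not in ("deep", "handcrafted", "both"):
            raise ValueError("mode must be deep, handcrafted or both")


# ---------------------------------------------------------------------------
# preprocessing helpers
# ---------------------------------------------------------------------------

def _stacks_for(cases, channel_mode):
    """Preprocess every tumor of every case on both canvases.

    Returns ``{(case_id, tumor_index): (ct_stack, pet_stack)}`` with raw
    (unnormalized) pixel stacks.
    """
    out = {}
    for c in cases:
        for k, t in enumerate(c.tumors):
            ct = prep.preprocess_tumor(t.ct, t.ct_mask, prep.DEFAULT_CANVAS_CT,
                                       channel_mode=channel_mode, modality="CT")
            pet = prep.preprocess_tumor(t.pet, t.pet_mask,
                                        prep.DEFAULT_CANVAS_PET,
                                        channel_mode=channel_mode,
                                        modality="PET")
            out[(c.case_id, k)] = (ct.pixels, pet.pixels)
    return out


def _index_tumor_idx(case):
    suvs = [t.suv for t in case.tumors]
    return int(np.argmax(suvs))


def _rows_for_outcome(cases, records, outcome):
    """Analysis rows: (case_id, tumor_index, clinical dict, record).

    OS/RFS/DC use each case's index tumor; LC is per tumor with the tumor's
    own SUV as the SUV covariate.
    """
    rows = []
    if outcome == "LC":
        by_key = {(r.case_id, r.tumor_index): r for r in records["LC"]}
        for c in cases:
            for k, t in enumerate(c.tumors):
                r = by_key.get((c.case_id, k))
                if r is None:
                    continue
                clin = {"age": c.clinical.age, "gender": c.clinical.gender,
                        "SUV": t.suv, "dose": c.clinical.dose}
                rows.append((c.case_id, k, clin, r))
    else:
        by_case = {r.case_id: r for r in records[outcome]}
        for c in cases:
            r = by_case.get(c.case_id)
            if r is None:
                continue
            k = _index_tumor_idx(c)
            clin = {"age": c.clinical.age, "gender": c.clinical.gender,
                    "SUV": c.clinical.suv_max, "dose": c.clinical.dose}
            rows.append((c.case_id, k, clin, r))
    return rows


# ---------------------------------------------------------------------------
# deep arm
# ---------------------------------------------------------------------------

def run_deep(config: RunConfig, cases=None, records=None):
    """Run the deep arm for every configured outcome.

    Returns the report dict (JSON-ready): per outcome the selected
    predictors with hazard ratios and p-values, the test-set concordance (or
    None when nothing is selected), training-set logrank cut-offs and
    Kaplan-Meier step curves for each selected predictor, and optionally a
    random-survival-forest pass over the same six predictors.
    """
    config.validate()
    if cases is None:
        cases, records = generate_cohort(config.cohort)
    train_ids, test_ids = split_train_test(cases, config.train_fraction,
                                           config.seed)
    stacks = _stacks_for(cases, config.channel_mode)

    trunk = {}
    if config.init == "cae":
        # pre-train on a second, disjoint synthetic set
        pre_spec = CohortSpec(n_cases=max(40, config.cohort.n_cases // 2),
                              seed=config.cohort.seed + 90001)
        pre_cases, _ = generate_cohort(pre_spec)
        pre_stacks = _stacks_for(pre_cases, config.channel_mode)
        for mod, side in (("ct", prep.DEFAULT_CANVAS_CT),
                          ("pet", prep.DEFAULT_CANVAS_PET)):
            arr = np.stack([v[0 if mod == "ct" else 1]
                            for v in pre_stacks.values()])
            spec = RiskNetSpec(input_side=side).desk_scale(
                epochs=config.epochs, learning_rate=config.learning_rate)
            trunk[mod], _ = pretrain_cae(arr, spec, epochs=config.cae_epochs,
                                         seed=config.seed + 17)

    report = {"mode": "deep", "seed": config.seed,
              "channel_mode": config.channel_mode,
              "train_ids": train_ids, "test_ids": test_ids, "outcomes": {}}
    for outcome in config.outcomes:
        entry, _ = _run_deep_outcome(config, cases, records, outcome,
                                     stacks, train_ids, test_ids, trunk)
        report["outcomes"][outcome] = entry
    return report


def _run_deep_outcome(config, cases, records, outcome, stacks,
                      train_ids, test_ids, trunk):
    rows = _rows_for_outcome(cases, records, outcome)
    is_train = np.array([cid in set(train_ids) for cid, *_ in rows])
    time = np.array([r.time for *_, r in rows])
    event = np.array([r.event for *_, r in rows])

    risk_cols = {}
    for mod, side in (("ct", prep.DEFAULT_CANVAS_CT),
                      ("pet", prep.DEFAULT_CANVAS_PET)):
        arr = np.stack([stacks[(cid, k)][0 if mod == "ct" else 1]
                        for cid, k, *_ in rows])
        lo, hi = prep.fit_intensity_range(arr[is_train])
        arr = prep.apply_intensity_range(arr, lo, hi)
        spec = RiskNetSpec(input_side=side).desk_scale(
            epochs=config.epochs, learning_rate=config.learning_rate)
        net = build_risk_net(spec, seed=config.seed + (1 if mod == "ct" else 2))
        if config.init == "cae":
            net.load_trunk(trunk[mod])
        net, _, _ = train_risk_net(net, arr[is_train], time[is_train],
                                   event[is_train], seed=config.seed + 3)
        risk_cols[f"{mod.upper()}_risk"] = score_risks(net, arr)

    X = pd.DataFrame({
        "CT_risk": risk_cols["CT_risk"],
        "PET_risk": risk_cols["PET_risk"],
        "age": [clin["age"] for _, _, clin, _ in rows],
        "gender": [clin["gender"] for _, _, clin, _ in rows],
        "SUV": [clin["SUV"] for _, _, clin, _ in rows],
        "dose": [clin["dose"] for _, _, clin, _ in rows],
    })
    entry = _stepwise_report(config, X, time, event, is_train)
    # per-branch ranking accuracy of the raw learned risks on the test set
    entry["branch_c_index"] = {}
    for nm in ("CT_risk", "PET_risk"):
        try:
            entry["branch_c_index"][nm] = concordance_index(
                X.loc[~is_train, nm].to_numpy(), time[~is_train],
                event[~is_train], kind="risk")
        except ValueError:
            entry["branch_c_index"][nm] = None
    return entry, (X, time, event, is_train)


def _stepwise_report(config, X, time, event, is_train):
    """Stepwise Cox on the training rows, scored on the test rows; cut-offs
    and KM curves for each selected predictor, fitted on training data."""
    fit = stepwise_select(X[is_train], time[is_train], event[is_train],
                          alpha=config.alpha)
    entry = {
        "selected": list(fit.selected),
        "coefficients": fit.coefficients,
        "hazard_ratios": fit.hazard_ratios,
        "p_values": fit.p_values,
        "c_index": None,
        "cutoffs": {},
        "km": {},
    }
    if fit.is_empty:
        return entry
    beta = np.array([fit.coefficients[nm] for nm in fit.selected])
    risk_test = X.loc[~is_train, fit.selected].to_numpy() @ beta
    try:
        entry["c_index"] = concordance_index(
            risk_test, time[~is_train], event[~is_train], kind="risk")
    except ValueError:
        entry["c_index"] = None
    for nm in fit.selected:
        vals = X.loc[is_train, nm].to_numpy()
        try:
            cut = optimal_cutoff(vals, time[is_train], event[is_train])
        except ValueError:
            continue
        entry["cutoffs"][nm] = {
            "threshold": cut.threshold,
            "logrank_statistic": cut.logrank_statistic,
            "p_value": cut.p_value,
            "n_low": cut.n_low, "n_high": cut.n_high,
        }
        low = vals <= cut.threshold
        km = {}
        for label, sel in (("low", low), ("high", ~low)):
            curve = kaplan_meier(time[is_train][sel], event[is_train][sel])
            km[label] = {"times": curve.times.tolist(),
                         "survival": curve.survival.tolist()}
        entry["km"][nm] = km
    if config.run_rsf:
        entry["rsf"] = _rsf_pass(config, X, time, event, is_train)
    return entry


def _rsf_pass(config, X, time, event, is_train):
    forest = fit_forest(X[is_train], time[is_train], event[is_train],
                        spec=config.forest)
    err = oob_error(forest, X[is_train])
    importances = vimp(forest, X[is_train])
    Xt = X[~is_train].to_numpy(dtype=float)
    risks = np.array([risk_score(forest, x, config.rsf_horizon) for x in Xt])
    try:
        c = concordance_index(risks, time[~is_train], event[~is_train],
                              kind="risk")
    except ValueError:
        c = None
    return {"oob_error": err, "vimp": importances, "c_index": c,
            "horizon": config.rsf_horizon}


# ---------------------------------------------------------------------------
# hand-crafted arm
# ---------------------------------------------------------------------------

def run_handcrafted(config: RunConfig, cases=None, records=None):
    """Hand-crafted radiomics arm, same report schema as the deep arm."""
    config.validate()
    if cases is None:
        cases, records = generate_cohort(config.cohort)
    train_ids, test_ids = split_train_test(cases, config.train_fraction,
                                           config.seed)
    report = {"mode": "handcrafted", "seed": config.seed,
              "channel_mode": config.channel_mode,
              "train_ids": train_ids, "test_ids": test_ids, "outcomes": {}}
    for outcome in config.outcomes:
        recs = records[outcome]
        if outcome == "LC":
            # per-tumor outcome: keep each case's index-tumor record so the
            # case-level feature extraction stays well defined
            idx = {c.case_id: _index_tumor_idx(c) for c in cases}
            recs = [r for r in recs if r.tumor_index == idx.get(r.case_id)]
        fit, c_index, _ = handcrafted_pipeline(
            cases, recs, train_ids, test_ids, alpha=config.alpha)
        report["outcomes"][outcome] = {
            "selected": list(fit.selected),
            "coefficients": fit.coefficients,
            "hazard_ratios": fit.hazard_ratios,
            "p_values": fit.p_values,
            "c_index": c_index,
            "cutoffs": {},
            "km": {},
        }
    return report


def run_combined(config: RunConfig, cases=None, records=None):
    """Concatenate both predictor families into one stepwise Cox.

    Per outcome: the trained CT/PET risks, the radiomics principal
    components of the training-fitted PCA, and the clinical factors enter
    a single backward-stepwise Cox. This is the package's interpretation
    of modelling "the combination" of the two feature families.
    """
    from .radiomics import feature_vector, fit_pca

    config.validate()
    if cases is None:
        cases, records = generate_cohort(config.cohort)
    train_ids, test_ids = split_train_test(cases, config.train_fraction,
                                           config.seed)
    stacks = _stacks_for(cases, config.channel_mode)
    feats = {}
    for c in cases:
        t = c.tumors[_index_tumor_idx(c)]
        feats[c.case_id] = feature_vector(t.ct[..., 1], t.ct_mask,
                                          t.pet[..., 1], t.pet_mask)

    report = {"mode": "combined", "seed": config.seed,
              "channel_mode": config.channel_mode,
              "train_ids": train_ids, "test_ids": test_ids, "outcomes": {}}
    for outcome in config.outcomes:
        _, (X, time, event, is_train) = _run_deep_outcome(
            config, cases, records, outcome, stacks, train_ids, test_ids,
            trunk={})
        rows = _rows_for_outcome(cases, records, outcome)
        F = np.array([feats[cid] for cid, *_ in rows])
        n_comp = min(10, max(1, int(is_train.sum()) - 10))
        pca = fit_pca(F[is_train], n_components=n_comp)
        Z = pca.transform(F)
        X = X.copy()
        for k in range(Z.shape[1]):
            X[f"PC{k + 1}"] = Z[:, k]
        report["outcomes"][outcome] = _stepwise_report(config, X, time,
                                                       event, is_train)
    return report


def run_forest(config: RunConfig, cases=None, records=None):
    """RSF-only pass over the six deep-arm predictors for each outcome."""
    cfg = RunConfig(**{**config.__dict__, "run_rsf": True})
    return run_deep(cfg, cases=cases, records=records)


# ---------------------------------------------------------------------------
# comparison and report validation
# ---------------------------------------------------------------------------

def compare_arms(report_deep, report_handcrafted):
    """Per-outcome c-index pairs and differences; None propagates."""
    out_d = report_deep["outcomes"]
    out_h = report_handcrafted["outcomes"]
    if set(out_d) != set(out_h):
        raise ValueError("reports cover different outcomes")
    if report_deep.get("train_ids") != report_handcrafted.get("train_ids"):
        raise ValueError("reports use different train/test splits")
    table = {}
    for outcome in out_d:
        cd = out_d[outcome]["c_index"]
        ch = out_h[outcome]["c_index"]
        diff = None if (cd is None or ch is None) else cd - ch
        table[outcome] = {"deep": cd, "handcrafted": ch, "difference": diff}
    return table


REPORT_SCHEMA = {
    "type": "object",
    "required": ["mode", "seed", "train_ids", "test_ids", "outcomes"],
    "outcome_entry": {
        "required": ["selected", "coefficients", "hazard_ratios",
                     "p_values", "c_index", "cutoffs", "km"],
    },
}


def validate_report(report, schema=None):
    """Check a report against the published schema; raises ValueError."""
    schema = schema or REPORT_SCHEMA
    for key in schema["required"]:
        if key not in report:
            raise ValueError(f"report missing key: {key}")
    if not isinstance(report["outcomes"], dict):
        raise ValueError("outcomes must be a mapping")
    for outcome, entry in report["outcomes"].items():
        for key in schema["outcome_entry"]["required"]:
            if key not in entry:
                raise ValueError(f"outcome {outcome} missing key: {key}")
        c = entry["c_index"]
        if c is not None and not (0.0 <= float(c) <= 1.0):
            raise ValueError(f"outcome {outcome}: c_index out of [0, 1]")
        if sorted(entry["hazard_ratios"]) != sorted(entry["coefficients"]):
            raise ValueError(f"outcome {outcome}: HR/coefficient key mismatch")
    return True


def write_report(report, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    return path
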