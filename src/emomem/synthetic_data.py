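"""Dual-process generative simulator for the pooled seven-study design.

The generator produces trial tables with the statistical structure the
analysis pipeline assumes, with known ground truth for parameter-recovery
and calibration experiments.

Generative model, per old item of affective category ``c``:

1. the item is *recollected* with probability ``r_c`` (a high-threshold
   process; participant, study-group, and group shifts enter on the probit
   scale) -> response "remember"; the source category is reported correctly
   with probability ``rho_rec_c``, otherwise a wrong category is drawn from
   the attribution-bias weights;
2. otherwise a familiarity strength ``x ~ Normal(f_c, 1)`` is drawn and
   compared with ``criterion_know``: above -> response "know" (source
   correct with probability ``rho_fam_c``, else a bias draw), below ->
   response "new".

New items produce a false "remember" with probability ``epsilon``; otherwise
``x ~ Normal(0, 1)`` against the same criterion yields "know" or "new".
False-alarm attributions are drawn from the bias weights.  Old/New blocks
collapse remember/know responses into "old".

Because recollection is a threshold process and familiarity an
equal-variance signal-detection process, the Remember/Know independence
scoring in :mod:`emomem.indices` is exactly well-specified: the expected
recollection d' is ``z(r_c) - z(epsilon)`` and the expected familiarity d'
is ``f_c`` (see :func:`expected_indices`).

Default parameter values live in ``configs/default_simulation.yaml``, not in
code, and qualitatively mirror a recollection-driven source-memory advantage
for emotional contexts that is amplified by pre-encoding stress, with no
item-memory category effect.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from emomem.trial_io import TRIAL_COLUMNS, validate_trials
from emomem.indices import build_index_table, unbiased_hit_rate


@dataclass(frozen=True)
class CategoryTruth:
    """Ground-truth parameters for one affective category.

    r : recollection probability for old items (high-threshold), in [0, 1]
    f : familiarity sensitivity (mean strength of old items), d'-units
    rho_rec : P(correct source attribution | recollected)
    rho_fam : P(correct source attribution | familiarity-only recognition)
    """

    r: float
    f: float
    rho_rec: float
    rho_fam: float

    def validate(self) -> None:
        for name in ("r", "rho_rec", "rho_fam"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GroupEffect:
    """Additive probit-scale shifts applied to one experimental group."""

    r_shift: float = 0.0
    f_shift: float = 0.0
    rho_rec_shift: Mapping[str, float] = field(default_factory=dict)
    rho_fam_shift: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class GroundTruth:
    """Population-level generative parameters."""

    categories: Mapping[str, CategoryTruth]
    epsilon: float = 0.02
    criterion_know: float = 1.0
    bias: Mapping[str, float] = field(default_factory=dict)
    sigma_participant: float = 0.0
    sigma_studygroup: float = 0.0
    group_effects: Mapping[str, GroupEffect] = field(default_factory=dict)

    def validate(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon={self.epsilon} outside [0, 1]")
        if self.sigma_participant < 0 or self.sigma_studygroup < 0:
            raise ValueError("random-intercept SDs must be nonnegative")
        for cat, ct in self.categories.items():
            ct.validate()
            if self.bias and self.bias.get(cat, 1.0) <= 0:
                raise ValueError(f"bias weight for {cat} must be positive")

    def bias_weight(self, cat: str) -> float:
        return self.bias.get(cat, 1.0) if self.bias else 1.0


@dataclass(frozen=True)
class StudyGroupBlock:
    """One study x group cell of the pooled design."""

    study: str
    group: str
    n_participants: int
    retrieval_task: str
    encoding_instruction: str
    environment: str
    categories: tuple[str, ...]
    n_old_per_category: int
    n_new: int

    def validate(self) -> None:
        if min(self.n_participants, self.n_old_per_category, self.n_new) <= 0:
            raise ValueError(f"block {self.study}/{self.group}: counts must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    """Design layout plus ground truth plus seed."""

    design: tuple[StudyGroupBlock, ...]
    truth: GroundTruth
    seed: int = 0

    def validate(self) -> None:
        self.truth.validate()
        for block in self.design:
            block.validate()
            for c in block.categories:
                if c not in self.truth.categories:
                    raise ValueError(f"no ground truth for category {c!r}")


_PUN = ("pleasant", "unpleasant", "neutral")
_UN = ("unpleasant", "neutral")

#: The 11 study-group blocks of the pooled design (7 studies, N = 333).
_TABLE1 = (
    StudyGroupBlock("S1", "control", 29, "old_new", "binding", "EEG", _PUN, 48, 144),
    StudyGroupBlock("S2", "control", 30, "remember_know", "free_viewing", "EEG", _PUN, 60, 180),
    StudyGroupBlock("S3", "control", 30, "remember_know", "binding", "EEG", _PUN, 60, 90),
    StudyGroupBlock("S3", "stress", 39, "remember_know", "binding", "EEG", _PUN, 60, 90),
    StudyGroupBlock("S3", "stress_delay", 18, "remember_know", "binding", "EEG", _PUN, 60, 90),
    StudyGroupBlock("S4", "control", 24, "old_new", "binding", "EEG", _UN, 48, 96),
    StudyGroupBlock("S4", "stress", 32, "old_new", "binding", "EEG", _UN, 48, 96),
    StudyGroupBlock("S5", "control", 29, "remember_know", "binding", "MRI", _PUN, 44, 132),
    StudyGroupBlock("S6", "control", 32, "remember_know", "binding", "MRI", _PUN, 44, 66),
    StudyGroupBlock("S6", "stress", 40, "remember_know", "binding", "MRI", _PUN, 44, 66),
    StudyGroupBlock("S7", "control", 30, "remember_know", "binding", "eye_tracker", _PUN, 44, 132),
)


def table1_design(n_participants: int | None = None) -> tuple[StudyGroupBlock, ...]:
    """The pooled 11-block design, optionally rescaled to a smaller N.

    With ``n_participants`` given, block sizes are reallocated proportionally
    (largest-remainder rounding, at least 2 participants per block) so the
    design keeps its structure at reduced scale.
    """
    if n_participants is None:
        return _TABLE1
    total = sum(b.n_participants for b in _TABLE1)
    raw = [b.n_participants * n_participants / total for b in _TABLE1]
    counts = [max(2, int(x)) for x in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - int(raw[i]), reverse=True)
    i = 0
    while sum(counts) < n_participants:
        counts[rema[i % len(rema)]] += 1
        i += 1
    return tuple(
        StudyGroupBlock(
            b.study, b.group, n, b.retrieval_task, b.encoding_instruction,
            b.environment, b.categories, b.n_old_per_category, b.n_new,
        )
        for b, n in zip(_TABLE1, counts)
    )


def _probit(p: float) -> float:
    return float(norm.ppf(p))


def _shifted_prob(p: float, shift: float) -> float:
    """Apply a probit-scale shift, keeping degenerate probabilities fixed."""
    if shift == 0.0 or p <= 0.0 or p >= 1.0:
        return min(max(p, 0.0), 1.0)
    return float(norm.cdf(_probit(p) + shift))


def _wrong_weights(truth: GroundTruth, true_cat: str, cats: Sequence[str]) -> tuple[list[str], np.ndarray]:
    others = [c for c in cats if c != true_cat]
    w = np.array([truth.bias_weight(c) for c in others], dtype=float)
    return others, w / w.sum()


def _all_weights(truth: GroundTruth, cats: Sequence[str]) -> np.ndarray:
    w = np.array([truth.bias_weight(c) for c in cats], dtype=float)
    return w / w.sum()


def simulate_trials(config: SimulationConfig, seed: int | None = None):
    """Generate a validated trial table plus its ground-truth record.

    Deterministic under a fixed seed (``seed`` overrides ``config.seed``).
    Returns ``(trials, truth_record)`` where ``truth_record`` is a plain
    JSON-serializable dict of every generative parameter actually used.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    truth = config.truth

    frames = []
    for block in config.design:
        cats = list(block.categories)
        ge = truth.group_effects.get(block.group, GroupEffect())
        v_sg = rng.normal(0.0, truth.sigma_studygroup) if truth.sigma_studygroup else 0.0
        all_w = _all_weights(truth, cats)

        for p_idx in range(block.n_participants):
            pid = f"{block.group}{p_idx + 1:03d}"
            u = rng.normal(0.0, truth.sigma_participant) if truth.sigma_participant else 0.0
            shift = u + v_sg

            n_old = block.n_old_per_category * len(cats)
            cat_arr = np.repeat(cats, block.n_old_per_category)
            resp = np.empty(n_old, dtype=object)
            src = np.full(n_old, None, dtype=object)

            for c in cats:
                m = cat_arr == c
                nc = int(m.sum())
                ct = truth.categories[c]
                r_eff = _shifted_prob(ct.r, shift + ge.r_shift)
                f_eff = ct.f + shift + ge.f_shift
                rho_rec = _shifted_prob(ct.rho_rec, ge.rho_rec_shift.get(c, 0.0))
                rho_fam = _shifted_prob(ct.rho_fam, ge.rho_fam_shift.get(c, 0.0))
                others, w_wrong = _wrong_weights(truth, c, cats)

                rec = rng.random(nc) < r_eff
                strength = rng.normal(f_eff, 1.0, nc)
                know = ~rec & (strength > truth.criterion_know)
                r_c = np.where(rec, "remember", np.where(know, "know", "new"))
                resp[m] = r_c

                recognized = rec | know
                correct_p = np.where(rec, rho_rec, rho_fam)
                is_correct = rng.random(nc) < correct_p
                s_c = np.full(nc, None, dtype=object)
                s_c[recognized & is_correct] = c
                n_wrong = int((recognized & ~is_correct).sum())
                if n_wrong and others:
                    s_c[recognized & ~is_correct] = rng.choice(others, size=n_wrong, p=w_wrong)
                src[m] = s_c

            # new items
            nn = block.n_new
            false_rem = rng.random(nn) < truth.epsilon
            x_new = rng.normal(0.0, 1.0, nn)
            new_resp = np.where(
                false_rem, "remember",
                np.where(x_new > truth.criterion_know, "know", "new"),
            )
            new_src = np.full(nn, None, dtype=object)
            fa = new_resp != "new"
            n_fa = int(fa.sum())
            if n_fa:
                new_src[fa] = rng.choice(cats, size=n_fa, p=all_w)

            all_resp = np.concatenate([resp, new_resp])
            all_src = np.concatenate([src, new_src])
            if block.retrieval_task == "old_new":
                all_resp = np.where(np.isin(all_resp, ("remember", "know")), "old", all_resp)

            n_trials = n_old + nn
            frames.append(pd.DataFrame({
                "participant_id": pid,
                "study": block.study,
                "group": block.group,
                "environment": block.environment,
                "encoding_instruction": block.encoding_instruction,
                "retrieval_task": block.retrieval_task,
                "n_new_items": nn,
                "item_id": (
                    [f"o{i}" for i in range(n_old)] + [f"n{i}" for i in range(nn)]
                ),
                "item_status": ["old"] * n_old + ["new"] * nn,
                "context_category": np.concatenate([cat_arr, np.full(nn, None, dtype=object)]),
                "recognition_response": all_resp,
                "source_response": all_src,
            }))

    trials = validate_trials(pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS])
    return trials, ground_truth_record(config)


def ground_truth_record(config: SimulationConfig) -> dict:
    """JSON-serializable record of the generative parameters and design."""
    rec = {
        "seed": config.seed,
        "truth": {
            "epsilon": config.truth.epsilon,
            "criterion_know": config.truth.criterion_know,
            "bias": dict(config.truth.bias),
            "sigma_participant": config.truth.sigma_participant,
            "sigma_studygroup": config.truth.sigma_studygroup,
            "categories": {c: asdict(ct) for c, ct in config.truth.categories.items()},
            "group_effects": {
                g: {
                    "r_shift": e.r_shift,
                    "f_shift": e.f_shift,
                    "rho_rec_shift": dict(e.rho_rec_shift),
                    "rho_fam_shift": dict(e.rho_fam_shift),
                }
                for g, e in config.truth.group_effects.items()
            },
        },
        "design": [asdict(b) for b in config.design],
    }
    return json.loads(json.dumps(rec))


def expected_indices(
    config: SimulationConfig,
    group: str = "control",
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Closed-form population expectations of every index, per category.

    Only defined at the population level: both random-intercept SDs must be
    zero.  Expectations assume equal numbers of old items per category, as
    in every block of the pooled design.

    Returns one row per category with expected recognition rates, d' values
    (no extreme-rate adjustment; degenerate rates yield NaN), and Hu per
    stratum computed from expected counts (the large-sample limit of the
    simulated indices).
    """
    config.validate()
    truth = config.truth
    if truth.sigma_participant != 0.0 or truth.sigma_studygroup != 0.0:
        raise ValueError("expectations are population-level: random-intercept SDs must be 0")
    cats = list(categories) if categories is not None else sorted(truth.categories)
    ge = truth.group_effects.get(group, GroupEffect())

    k = truth.criterion_know
    eps = truth.epsilon
    p_fa_rem = eps
    p_fa_know = (1.0 - eps) * float(norm.cdf(-k))
    p_fa = p_fa_rem + p_fa_know

    def zq(p: float) -> float:
        return float(norm.ppf(p)) if 0.0 < p < 1.0 else float("nan")

    per_cat = {}
    for c in cats:
        ct = truth.categories[c]
        r = _shifted_prob(ct.r, ge.r_shift)
        f = ct.f + ge.f_shift
        per_cat[c] = {
            "r": r,
            "p_rem": r,
            "p_know": (1.0 - r) * float(norm.cdf(f - k)),
            "rho_rec": _shifted_prob(ct.rho_rec, ge.rho_rec_shift.get(c, 0.0)),
            "rho_fam": _shifted_prob(ct.rho_fam, ge.rho_fam_shift.get(c, 0.0)),
        }

    # expected Hu from expected counts, one old item per category cell
    def hu_stratum(stratum: str) -> dict[str, float]:
        rate = {}
        rho = {}
        for c in cats:
            pc = per_cat[c]
            if stratum == "remember":
                rate[c] = pc["p_rem"]
                rho[c] = pc["rho_rec"]
            elif stratum == "know":
                rate[c] = pc["p_know"]
                rho[c] = pc["rho_fam"]
            else:
                rate[c] = pc["p_rem"] + pc["p_know"]
                rho[c] = (
                    (pc["p_rem"] * pc["rho_rec"] + pc["p_know"] * pc["rho_fam"]) / rate[c]
                    if rate[c] > 0 else 0.0
                )
        out = {}
        for c in cats:
            hits = rate[c] * rho[c]
            incorrect = rate[c] * (1.0 - rho[c])
            chosen = 0.0
            for d in cats:
                if d == c:
                    chosen += rate[d] * rho[d]
                else:
                    others, w = _wrong_weights(truth, d, cats)
                    chosen += rate[d] * (1.0 - rho[d]) * float(w[others.index(c)])
            if hits + incorrect <= 0 or chosen <= 0:
                out[c] = float("nan")
            else:
                out[c] = (hits / (hits + incorrect)) * (hits / chosen)
        return out

    hu_all = {s: hu_stratum(s) for s in ("overall", "remember", "know")}

    rows = []
    for c in cats:
        pc = per_cat[c]
        p_old = pc["p_rem"] + pc["p_know"]
        with np.errstate(divide="ignore", invalid="ignore"):
            fam_hit = pc["p_know"] / (1.0 - pc["p_rem"]) if pc["p_rem"] < 1 else float("nan")
            fam_fa = p_fa_know / (1.0 - p_fa_rem) if p_fa_rem < 1 else float("nan")
        rows.append({
            "category": c,
            "p_old": p_old,
            "p_remember": pc["p_rem"],
            "p_know": pc["p_know"],
            "p_fa": p_fa,
            "p_fa_remember": p_fa_rem,
            "p_fa_know": p_fa_know,
            "d_prime": zq(p_old) - zq(p_fa),
            "recollection_d_prime": zq(pc["p_rem"]) - zq(p_fa_rem),
            "familiarity_d_prime": zq(fam_hit) - zq(fam_fa),
            "hu_overall": hu_all["overall"][c],
            "hu_remember": hu_all["remember"][c],
            "hu_know": hu_all["know"][c],
        })
    return pd.DataFrame(rows)


def default_config(seed: int = 0) -> SimulationConfig:
    """Load the packaged default simulation configuration."""
    ref = importlib.resources.files("emomem").joinpath("configs/default_simulation.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_config(path, seed=seed)


def load_config(path, seed: int | None = None) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw, seed=seed)


def config_from_dict(raw: Mapping, seed: int | None = None) -> SimulationConfig:
    t = raw["truth"]
    truth = GroundTruth(
        categories={c: CategoryTruth(**v) for c, v in t["categories"].items()},
        epsilon=float(t.get("epsilon", 0.02)),
        criterion_know=float(t.get("criterion_know", 1.0)),
        bias=dict(t.get("bias", {})),
        sigma_participant=float(t.get("sigma_participant", 0.0)),
        sigma_studygroup=float(t.get("sigma_studygroup", 0.0)),
        group_effects={
            g: GroupEffect(
                r_shift=float(e.get("r_shift", 0.0)),
                f_shift=float(e.get("f_shift", 0.0)),
                rho_rec_shift=dict(e.get("rho_rec_shift", {})),
                rho_fam_shift=dict(e.get("rho_fam_shift", {})),
            )
            for g, e in t.get("group_effects", {}).items()
        },
    )
    design_raw = raw.get("design", "table1")
    if design_raw == "table1":
        design = table1_design(raw.get("n_participants"))
    else:
        design = tuple(StudyGroupBlock(
            study=b["study"], group=b["group"], n_participants=int(b["n_participants"]),
            retrieval_task=b["retrieval_task"],
            encoding_instruction=b["encoding_instruction"],
            environment=b["environment"], categories=tuple(b["categories"]),
            n_old_per_category=int(b["n_old_per_category"]), n_new=int(b["n_new"]),
        ) for b in design_raw)
    cfg = SimulationConfig(
        design=design,
        truth=truth,
        seed=int(raw.get("seed", 0)) if seed is None else int(seed),
    )
    cfg.validate()
    return cfg


def recovery_experiment(
    config: SimulationConfig,
    n_reps: int,
    *,
    response: str = "d_prime",
    analysis_set: str = "overall",
    term: str = "affective_category",
    base_terms: Sequence[str] = (),
    alpha: float = 0.05,
    sign_coefficients: Sequence[str] | None = None,
    seed: int | None = None,
) -> dict:
    """Simulate -> score -> fit replicates and summarize test calibration.

    Per replicate, the trial table is generated, scored into the index
    table, restricted to the requested analysis set (``overall`` rows or the
    remember/know rows with ``by_memory_type``), and the likelihood-ratio
    test of ``term`` (added to ``base_terms``) is run.

    Returns a summary dict with the rejection rate at ``alpha``, the
    per-replicate p-values and coefficient estimates of the added term, and
    (when ``sign_coefficients`` is given) the rate of replicates that both
    reject and estimate every named coefficient positive.  Fit failures are
    counted, not fatal.
    """
    from emomem.mixed_models import ModelSpec, fit_lmm, lr_test

    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    root = np.random.default_rng(config.seed if seed is None else seed)
    rep_seeds = root.integers(0, 2**31 - 1, size=n_reps)

    records = []
    n_failed = 0
    for rs in rep_seeds:
        try:
            trials, _ = simulate_trials(config, seed=int(rs))
            table = build_index_table(trials)
            if analysis_set == "overall":
                sub = table[table["memory_type"] == "overall"]
            else:
                sub = table[table["memory_type"].isin(("remember", "know"))]
            small = fit_lmm(sub, ModelSpec(response=response, fixed_terms=tuple(base_terms)))
            large = fit_lmm(
                sub, ModelSpec(response=response, fixed_terms=tuple(base_terms) + (term,))
            )
            lrt = lr_test(small, large)
            ests = {
                name: float(val)
                for name, val in large.params.items()
                if name not in small.params.index
            }
            records.append({"seed": int(rs), "p": lrt.p, "chi_square": lrt.chi_square,
                            "df": lrt.df, "estimates": ests})
        except Exception as exc:  # noqa: BLE001 - failures are data, not fatal
            n_failed += 1
            records.append({"seed": int(rs), "error": str(exc)})

    ok = [r for r in records if "p" in r]
    rej = [r for r in ok if r["p"] < alpha]
    summary = {
        "n_reps": n_reps,
        "n_failed": n_failed,
        "alpha": alpha,
        "term": term,
        "rejection_rate": len(rej) / len(ok) if ok else float("nan"),
        "replicates": records,
    }
    if sign_coefficients is not None:
        good = [
            r for r in rej
            if all(r["estimates"].get(c, float("nan")) > 0 for c in sign_coefficients)
        ]
        summary["sign_recovery_rate"] = len(good) / len(ok) if ok else float("nan")
    return summary
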