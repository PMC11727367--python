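"""Brute-force reimplementation of the memory indices for cross-checking.

Everything here is computed by direct enumeration over trial dicts with
plain Python loops — no code shared with the package — so it can serve as
an independent oracle for the vectorized scoring pipeline.
"""

from __future__ import annotations

from scipy.stats import norm

OLD_CALLS = {"remember", "know", "old"}


def _adj(s: int, n: int) -> float:
    if s == 0:
        return 1.0 / (2 * n)
    if s == n:
        return 1.0 - 1.0 / (2 * n)
    return s / n


def _z(p: float) -> float:
    return float(norm.ppf(p))


def _hu(trials, participant, stratum, category) -> float | None:
    """Unbiased hit rate by direct enumeration; None when undefined."""
    hits = incorrect = chosen = 0
    for t in trials:
        if t["participant"] != participant or t["item_status"] != "old":
            continue
        resp = t["recognition_response"]
        if resp not in OLD_CALLS:
            continue
        if stratum != "overall" and resp != stratum:
            continue
        src = t.get("source_response")
        if src is None:
            continue
        if t["context_category"] == category:
            if src == category:
                hits += 1
            else:
                incorrect += 1
        if src == category:
            chosen += 1
    if hits + incorrect == 0 or chosen == 0:
        return None
    return (hits / (hits + incorrect)) * (hits / chosen)


def oracle_indices(trials: list[dict]) -> dict:
    """All indices for every participant x category (x memory type) cell.

    ``trials`` is a list of dicts with the trial-table fields plus the
    study-prefixed ``participant`` label.  Returns
    ``{(participant, memory_type, category): {"d_prime": v|None, "hu": v|None}}``.
    """
    out = {}
    participants = sorted({t["participant"] for t in trials})
    for p in participants:
        mine = [t for t in trials if t["participant"] == p]
        task = mine[0]["retrieval_task"]
        news = [t for t in mine if t["item_status"] == "new"]
        n_new = len(news)
        fa = sum(t["recognition_response"] in OLD_CALLS for t in news)
        r_fa = sum(t["recognition_response"] == "remember" for t in news)
        k_fa = sum(t["recognition_response"] == "know" for t in news)
        cats = sorted({t["context_category"] for t in mine if t["item_status"] == "old"})
        for c in cats:
            olds = [t for t in mine
                    if t["item_status"] == "old" and t["context_category"] == c]
            n_old = len(olds)
            hits = sum(t["recognition_response"] in OLD_CALLS for t in olds)
            d = _z(_adj(hits, n_old)) - _z(_adj(fa, n_new))
            out[(p, "overall", c)] = {"d_prime": d, "hu": _hu(mine, p, "overall", c)}
            if task != "remember_know":
                continue
            r_hits = sum(t["recognition_response"] == "remember" for t in olds)
            k_hits = sum(t["recognition_response"] == "know" for t in olds)
            rh, kh = _adj(r_hits, n_old), _adj(k_hits, n_old)
            rf, kf = _adj(r_fa, n_new), _adj(k_fa, n_new)
            d_rec = _z(rh) - _z(rf)
            hit_ratio = kh / (1 - rh)
            fa_ratio = kf / (1 - rf)
            if 0 < hit_ratio < 1 and 0 < fa_ratio < 1:
                d_fam = _z(hit_ratio) - _z(fa_ratio)
            else:
                d_fam = None
            out[(p, "remember", c)] = {"d_prime": d_rec, "hu": _hu(mine, p, "remember", c)}
            out[(p, "know", c)] = {"d_prime": d_fam, "hu": _hu(mine, p, "know", c)}
    return out


def random_trial_fixture(rng, max_trials: int = 200) -> list[dict]:
    """A random, invariant-respecting trial table as a list of dicts."""
    task = rng.choice(["old_new", "remember_know"])
    cats = ["pleasant", "neutral", "unpleasant"]
    if rng.random() < 0.25:
        cats = ["unpleasant", "neutral"]
    n_participants = int(rng.integers(1, 4))
    trials = []
    budget = int(rng.integers(12, max_trials + 1))
    per_p = max(6, budget // n_participants)
    for pi in range(n_participants):
        n_old_per_cat = max(1, per_p // (2 * len(cats)))
        n_new = max(1, per_p - n_old_per_cat * len(cats))
        base = {
            "participant": f"SX:p{pi}",
            "participant_id": f"p{pi}",
            "study": "SX",
            "group": str(rng.choice(["control", "stress", "stress_delay"])),
            "environment": str(rng.choice(["EEG", "MRI", "eye_tracker"])),
            "encoding_instruction": str(rng.choice(["binding", "free_viewing"])),
            "retrieval_task": task,
            "n_new_items": n_new,
        }
        old_calls = ["old", "new"] if task == "old_new" else ["remember", "know", "new"]
        item = 0
        for c in cats:
            for _ in range(n_old_per_cat):
                resp = str(rng.choice(old_calls))
                src = str(rng.choice(cats)) if resp != "new" else None
                trials.append({**base, "item_id": f"o{item}", "item_status": "old",
                               "context_category": c, "recognition_response": resp,
                               "source_response": src})
                item += 1
        for _ in range(n_new):
            # mostly correct rejections, some false alarms
            resp = str(rng.choice(old_calls, p=[0.2, 0.8] if task == "old_new"
                                  else [0.1, 0.15, 0.75]))
            src = str(rng.choice(cats)) if resp != "new" else None
            trials.append({**base, "item_id": f"n{item}", "item_status": "new",
                           "context_category": None, "recognition_response": resp,
                           "source_response": src})
            item += 1
    return trials
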