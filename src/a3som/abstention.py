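"""Post-hoc abstained classification.

Abstention is applied after training, to the sigmoid-head probabilities of a
fitted model. Two rules, each with one threshold per predicted class:

* **distance rule** — abstain when the largest output probability
  ``y_ic*`` falls (strictly) below ``beta_dist[c*]``. Fires for samples far
  from every learned class: candidate members of a *new* class.
* **ambiguity rule** — abstain when the margin between the two largest
  output probabilities falls (strictly) below ``beta_amb[c*]``. Fires inside
  class overlaps.

When both rules fire, the distance reason takes precedence (it is the one
that identifies new-class clusters on the map). Thresholds can be *local*
(per class) or *global* (shared); the local family contains the global one,
so a well-searched local front never does worse.

Quality of an abstained classifier is summarized by the accepted accuracy
``AA = |G ∩ A| / |A|`` (correct fraction among accepted predictions) and
the rejected error ``RE = |E ∩ R| / |E|`` (fraction of all errors that were
rejected), where G/E split samples by argmax correctness and A/R by the
abstention decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSet",
    "AbstainedPrediction",
    "AbstentionReport",
    "distance_rule",
    "ambiguity_rule",
    "apply_abstention",
    "calibrate_thresholds",
    "abstention_metrics",
    "threshold_sweep",
    "pareto_front",
    "ABSTAIN",
]

ABSTAIN = -1


@dataclass
class ThresholdSet:
    """Per-class abstention thresholds, each in [0, 1].

    ``scope`` is "global" when every per-class value (within each rule) is
    identical, "local" otherwise.
    """

    beta_dist: np.ndarray
    beta_amb: np.ndarray

    def __post_init__(self):
        self.beta_dist = np.asarray(self.beta_dist, dtype=float)
        self.beta_amb = np.asarray(self.beta_amb, dtype=float)
        if self.beta_dist.shape != self.beta_amb.shape:
            raise ValueError("beta_dist and beta_amb must have equal length")
        for name, b in (("beta_dist", self.beta_dist), ("beta_amb", self.beta_amb)):
            if np.any((b < 0) | (b > 1)):
                raise ValueError(f"{name} values must lie in [0, 1]")

    @property
    def n_classes(self) -> int:
        return self.beta_dist.shape[0]

    @property
    def scope(self) -> str:
        if (np.all(self.beta_dist == self.beta_dist[0])
                and np.all(self.beta_amb == self.beta_amb[0])):
            return "global"
        return "local"

    @classmethod
    def globally(cls, n_classes: int, dist: float = 0.0, amb: float = 0.0):
        """A global (shared-threshold) set, the degenerate local form."""
        return cls(np.full(n_classes, dist), np.full(n_classes, amb))

    def to_json(self, path=None) -> str:
        s = json.dumps(
            {"beta_dist": self.beta_dist.tolist(),
             "beta_amb": self.beta_amb.tolist()}, indent=2
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "ThresholdSet":
        """Accepts a JSON string or a path to a JSON file."""
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source) as fh:
                obj = json.load(fh)
        return cls(np.array(obj["beta_dist"]), np.array(obj["beta_amb"]))


@dataclass
class AbstainedPrediction:
    """Outcome for one sample: a class, or abstention with its reason."""

    decision: int  # class index, or ABSTAIN
    reason: str  # "none" | "distance" | "ambiguity"
    top_class: int
    top_prob: float
    runner_up_prob: float

    @property
    def abstained(self) -> bool:
        return self.decision == ABSTAIN


@dataclass
class AbstentionReport:
    """Decision regions and the AA/RE summary of an abstained run."""

    good: frozenset  # G: argmax correct
    error: frozenset  # E: argmax wrong
    accepted: frozenset  # A
    rejected: frozenset  # R
    aa: float
    re: float
    rejection_rate: float


def _top_two(prob_row: np.ndarray) -> tuple[int, float, float]:
    prob_row = np.asarray(prob_row, dtype=float)
    if prob_row.size == 0:
        raise ValueError("empty probability row")
    c_star = int(np.argmax(prob_row))
    top = float(prob_row[c_star])
    if prob_row.size < 2:
        return c_star, top, float("-inf")
    rest = np.delete(prob_row, c_star)
    return c_star, top, float(rest.max())


def distance_rule(prob_row: np.ndarray, thresholds: ThresholdSet) -> int:
    """1 (abstain) iff the top probability is strictly below its class's
    distance threshold; 0 otherwise. Equality accepts."""
    c_star, top, _ = _top_two(prob_row)
    return int(top < thresholds.beta_dist[c_star])


def ambiguity_rule(prob_row: np.ndarray, thresholds: ThresholdSet) -> int:
    """1 (abstain) iff the top-two margin is strictly below its class's
    ambiguity threshold; 0 otherwise. Needs at least two classes."""
    prob_row = np.asarray(prob_row, dtype=float)
    if prob_row.size < 2:
        raise ValueError("ambiguity rule needs at least two classes")
    c_star, top, second = _top_two(prob_row)
    return int((top - second) < thresholds.beta_amb[c_star])


def apply_abstention(
    probabilities: np.ndarray, thresholds: ThresholdSet
) -> list[AbstainedPrediction]:
    """Evaluate both rules per row: distance first, then ambiguity, else
    accept the argmax class."""
    P = np.atleast_2d(np.asarray(probabilities, dtype=float))
    out = []
    for row in P:
        c_star, top, second = _top_two(row)
        if distance_rule(row, thresholds):
            out.append(AbstainedPrediction(ABSTAIN, "distance", c_star, top, second))
        elif P.shape[1] >= 2 and ambiguity_rule(row, thresholds):
            out.append(AbstainedPrediction(ABSTAIN, "ambiguity", c_star, top, second))
        else:
            out.append(AbstainedPrediction(c_star, "none", c_star, top, second))
    return out


def calibrate_thresholds(
    probabilities: np.ndarray, mode: str = "both"
) -> ThresholdSet:
    """Mean-based threshold calibration on (training-set) predictions.

    For each class ``c``, over the samples whose argmax class is ``c``:
    the distance threshold is the mean of their top probabilities, the
    ambiguity threshold the mean of their top-two margins. A class with no
    assigned samples gets threshold 0 (it can never trigger abstention).
    ``mode`` zeroes the other rule's thresholds: "distance", "ambiguity",
    or "both".
    """
    if mode not in ("distance", "ambiguity", "both"):
        raise ValueError(f"unknown calibration mode {mode!r}")
    P = np.atleast_2d(np.asarray(probabilities, dtype=float))
    if P.size == 0:
        raise ValueError("empty probability matrix")
    C = P.shape[1]
    assigned = np.argmax(P, axis=1)
    top = P[np.arange(P.shape[0]), assigned]
    if C >= 2:
        part = np.partition(P, C - 2, axis=1)
        second = part[:, C - 2]
    else:
        second = np.zeros_like(top)
    margin = top - second

    beta_dist = np.zeros(C)
    beta_amb = np.zeros(C)
    for c in range(C):
        members = assigned == c
        if members.any():
            beta_dist[c] = float(np.mean(top[members]))
            beta_amb[c] = float(np.mean(margin[members]))
    if mode == "distance":
        beta_amb[:] = 0.0
    elif mode == "ambiguity":
        beta_dist[:] = 0.0
    return ThresholdSet(np.clip(beta_dist, 0, 1), np.clip(beta_amb, 0, 1))


def abstention_metrics(
    true_labels: np.ndarray, predictions: list[AbstainedPrediction]
) -> AbstentionReport:
    """AA and RE from the G/E (correctness) and A/R (abstention) partitions.

    Vacuous denominators: AA = 1 when nothing is accepted, RE = 1 when
    there are no errors to reject. With zero rejections AA reduces to plain
    accuracy and (when errors exist) RE to 0.
    """
    true_labels = np.asarray(true_labels)
    if true_labels.shape[0] != len(predictions):
        raise ValueError("true_labels and predictions length mismatch")
    idx = np.arange(true_labels.shape[0])
    argmax = np.array([p.top_class for p in predictions])
    rejected_mask = np.array([p.abstained for p in predictions])
    good = frozenset(idx[argmax == true_labels])
    error = frozenset(idx[argmax != true_labels])
    accepted = frozenset(idx[~rejected_mask])
    rejected = frozenset(idx[rejected_mask])
    aa = len(good & accepted) / len(accepted) if accepted else 1.0
    re = len(error & rejected) / len(error) if error else 1.0
    return AbstentionReport(
        good=good, error=error, accepted=accepted, rejected=rejected,
        aa=aa, re=re,
        rejection_rate=len(rejected) / max(len(predictions), 1),
    )


def _sweep_stats(P: np.ndarray, y: np.ndarray):
    """Per-sample statistics reused across sweep candidates."""
    C = P.shape[1]
    assigned = np.argmax(P, axis=1)
    top = P[np.arange(P.shape[0]), assigned]
    if C >= 2:
        second = np.partition(P, C - 2, axis=1)[:, C - 2]
    else:
        second = np.full_like(top, -np.inf)
    return assigned, top, assigned == y, top - second


def _sweep_eval(stat, rule: str, b: np.ndarray) -> tuple[float, float, float]:
    assigned, top, correct, margin = stat
    crit = top if rule == "distance" else margin
    rejected = crit < b[assigned]
    accepted = ~rejected
    n_err = np.sum(~correct)
    aa = float(np.mean(correct[accepted])) if accepted.any() else 1.0
    re = float(np.sum(rejected & ~correct) / n_err) if n_err else 1.0
    return float(np.mean(rejected)), aa, re


def threshold_sweep(
    probabilities: np.ndarray,
    true_labels: np.ndarray,
    rule: str = "distance",
    scope: str = "global",
    grid_resolution: int = 101,
    n_samples: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Trace (rejection_rate, AA, RE) while varying the thresholds of one
    rule; the other rule's thresholds stay at 0.

    Global scope sweeps one shared threshold over a uniform [0, 1] grid.
    Local scope explores the per-class hypercube by seeded uniform random
    search (``n_samples`` draws) *plus* the shared-threshold diagonal — the
    global configurations are a subset of the local space, so seeding the
    search with them guarantees the local front starts from the global one.
    """
    if rule not in ("distance", "ambiguity"):
        raise ValueError(f"unknown rule {rule!r}")
    if scope not in ("global", "local"):
        raise ValueError(f"unknown scope {scope!r}")
    P = np.atleast_2d(np.asarray(probabilities, dtype=float))
    y = np.asarray(true_labels)
    C = P.shape[1]
    stat = _sweep_stats(P, y)

    rows = []
    grid = np.linspace(0.0, 1.0, grid_resolution)
    if scope == "global":
        for t in grid:
            rej, aa, re = _sweep_eval(stat, rule, np.full(C, t))
            rows.append({"threshold": t, "rejection_rate": rej, "aa": aa, "re": re})
    else:
        rng = np.random.default_rng(seed)
        candidates = [np.full(C, t) for t in grid]
        candidates += list(rng.uniform(0.0, 1.0, size=(n_samples, C)))
        for b in candidates:
            rej, aa, re = _sweep_eval(stat, rule, b)
            rows.append(
                {"threshold": float(np.mean(b)), "rejection_rate": rej,
                 "aa": aa, "re": re,
                 **{f"beta_{c}": b[c] for c in range(C)}}
            )
    return pd.DataFrame(rows)


def pareto_front(
    curve: pd.DataFrame, metric: str = "re"
) -> pd.DataFrame:
    """Non-dominated points: maximal ``metric`` per rejection level.

    A point is kept iff no other point has <= rejection_rate and >= metric
    with at least one strict. Returned sorted by rejection rate.
    """
    pts = curve[["rejection_rate", metric]].to_numpy()
    order = np.lexsort((-pts[:, 1], pts[:, 0]))
    best = -np.inf
    keep = []
    for i in order:
        if pts[i, 1] > best:
            best = pts[i, 1]
            keep.append(i)
    return curve.iloc[keep].sort_values("rejection_rate").reset_index(drop=True)


def rejection_needed(curve: pd.DataFrame, metric: str, level: float) -> float:
    """Smallest rejection rate in ``curve`` reaching ``metric >= level``
    (inf if never reached)."""
    ok = curve[curve[metric] >= level]
    return float(ok["rejection_rate"].min()) if len(ok) else float("inf")
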