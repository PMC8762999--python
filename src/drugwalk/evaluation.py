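"""Decoy-ranking evaluation of disease prioritizations.

For every known drug-disease relationship in a validation set, the true
disease is re-ranked within a list of randomly selected decoy diseases
(99 by default, giving a rank in 1..100). Sweeping a rank threshold yields a
ranking ROC curve: sensitivity is the fraction of validation pairs whose
disease ranks at or above the threshold, and specificity the fraction of
decoys ranked below the disease. The area under this curve — equivalently
the mean of (n_lists - rank) / n_decoys — summarizes performance: 100%
means every disease ranked first, 50% means random ordering. Decoy draws
are repeated (50 times by default) and the per-repetition AUCs averaged.

Also provided: a random baseline in which the validation diseases are
replaced by uniform draws, and 10-fold cross-validation of the full model in
which each fold's drug-disease links are removed from the prior-knowledge
matrix and the seeds before the held-out pairs are scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import HeteroNetwork
from .propagation import ConvergenceError, build_seed, propagate
from .transition import LayerWeights, TransitionMatrix, build_transition

__all__ = [
    "ValidationSet",
    "RankingRecord",
    "AucSummary",
    "rank_pair",
    "ranking_auc",
    "evaluate",
    "cross_validate",
    "random_baseline",
    "score_drugs",
    "top_half_accuracy",
    "compare_models",
]

logger = logging.getLogger(__name__)

DEFAULT_N_DECOYS = 99
DEFAULT_REPETITIONS = 50


@dataclass
class ValidationSet:
    """Known drug-disease relationships, optionally with fold labels."""

    pairs: pd.DataFrame  # columns: drug_id, disease_id[, fold]

    def __post_init__(self) -> None:
        for col in ("drug_id", "disease_id"):
            if col not in self.pairs.columns:
                raise ValueError(f"validation set missing column {col!r}")
        if self.pairs.empty:
            raise ValueError("empty validation set")
        if self.pairs.duplicated(["drug_id", "disease_id"]).any():
            raise ValueError("duplicate drug-disease pairs in validation set")

    def __len__(self) -> int:
        return len(self.pairs)

    def known_diseases(self) -> dict[str, set[str]]:
        """Diseases known to be linked to each drug (decoy exclusion sets)."""
        out: dict[str, set[str]] = {}
        for g, d in zip(self.pairs["drug_id"], self.pairs["disease_id"]):
            out.setdefault(g, set()).add(d)
        return out

    def assign_folds(self, n_folds: int, rng: np.random.Generator) -> "ValidationSet":
        """Shuffle pairs and assign fold labels 1..n_folds round-robin."""
        df = self.pairs.sample(frac=1.0, random_state=rng).reset_index(drop=True)
        df["fold"] = np.arange(len(df)) % n_folds + 1
        return ValidationSet(df)


@dataclass
class RankingRecord:
    """The rank of one validation pair's disease among its decoys."""

    drug: str
    disease: str
    rank: float  # midrank under ties, hence possibly half-integral
    repetition: int
    n_decoys: int = DEFAULT_N_DECOYS

    @property
    def rank_int(self) -> int:
        """Integer rank, rounding half-integral midranks up (documented)."""
        return int(np.floor(self.rank + 0.5))


@dataclass
class AucSummary:
    """Ranking-ROC area under curve, as a percentage in [0, 100]."""

    auc: float
    per_repetition: list[float]
    curve: pd.DataFrame | None = None  # threshold, sensitivity, fpr
    n_pairs: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not -1e-9 <= self.auc <= 100 + 1e-9:
            raise ValueError(f"AUC {self.auc} outside [0, 100]")


def rank_pair(
    scores: dict[str, float],
    true_disease: str,
    decoys: list[str] | tuple[str, ...],
    tie_break: str = "midrank",
) -> float:
    """Rank of the true disease within itself plus its decoy list.

    rank = 1 + (number of decoys scoring strictly higher) plus a tie
    adjustment: ``midrank`` (default) adds half the tied decoys, ``best``
    none, ``worst`` all of them. The decoys must not contain the true
    disease and every ID must be scored.
    """
    if true_disease in decoys:
        raise ValueError(f"true disease {true_disease!r} appears among its decoys")
    if len(set(decoys)) != len(decoys):
        raise ValueError("duplicate decoys")
    try:
        s_true = scores[true_disease]
        s_dec = np.array([scores[d] for d in decoys], dtype=float)
    except KeyError as exc:
        raise KeyError(f"unscored disease {exc.args[0]!r}") from exc
    higher = int((s_dec > s_true).sum())
    ties = int((s_dec == s_true).sum())
    if tie_break == "midrank":
        return 1.0 + higher + ties / 2.0
    if tie_break == "best":
        return 1.0 + higher
    if tie_break == "worst":
        return 1.0 + higher + ties
    raise ValueError(f"unknown tie_break {tie_break!r}")


def ranking_auc(
    ranks: list[float] | np.ndarray, n_decoys: int = DEFAULT_N_DECOYS
) -> AucSummary:
    """Area under the ranking ROC curve for a collection of ranks.

    The curve sweeps thresholds k = 0..n_decoys+1: sensitivity(k) is the
    fraction of pairs with rank <= k, and the false positive rate the mean
    fraction of decoys occupying the top k positions. The trapezoid area
    equals the closed form mean((n_decoys + 1 - rank) / n_decoys), reported
    as a percentage.
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("no ranks to summarize")
    n_list = n_decoys + 1
    if (ranks < 1).any() or (ranks > n_list).any():
        raise ValueError(f"rank outside [1, {n_list}]")
    thresholds = np.arange(0, n_list + 1)
    sens = (ranks[None, :] <= thresholds[:, None]).mean(axis=1)
    # among the top k list positions, the true disease occupies one iff rank<=k
    fpr = (thresholds - sens * 1.0) / n_decoys
    fpr = np.clip(fpr, 0.0, 1.0)
    auc = float(np.trapezoid(sens, fpr)) * 100.0
    curve = pd.DataFrame({"threshold": thresholds, "sensitivity": sens, "fpr": fpr})
    return AucSummary(auc=auc, per_repetition=[auc], curve=curve, n_pairs=ranks.size)


def top_half_accuracy(ranks: list[float] | np.ndarray, n_decoys: int = DEFAULT_N_DECOYS) -> float:
    """Fraction of pairs ranked in the top half of their decoy list.

    One reasonable reading of 'accuracy' for a ranking protocol; reported as
    a fraction in [0, 1].
    """
    ranks = np.asarray(ranks, dtype=float)
    if ranks.size == 0:
        raise ValueError("no ranks")
    return float((ranks <= (n_decoys + 1) / 2).mean())


def compare_models(a: AucSummary, b: AucSummary) -> float:
    """Two-sided t-test p-value over per-repetition AUCs of two models."""
    from scipy import stats

    if len(a.per_repetition) < 2 or len(b.per_repetition) < 2:
        raise ValueError("need at least two repetitions per model to compare")
    return float(stats.ttest_ind(a.per_repetition, b.per_repetition).pvalue)


def score_drugs(
    net: HeteroNetwork,
    tm: TransitionMatrix,
    drugs: list[str] | set[str],
    weights: LayerWeights,
    r: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 10_000,
    strategy: str | None = None,
) -> tuple[dict[str, dict[str, float]], list[str]]:
    """Propagate from each drug once; return disease score maps and failures.

    The stationary disease probabilities depend only on the drug, so they are
    shared by every repetition and decoy draw downstream. Drugs whose
    propagation diverges are reported in the failure list and skipped.
    """
    strategy = strategy or tm.strategy
    scores: dict[str, dict[str, float]] = {}
    failed: list[str] = []
    for drug in sorted(set(drugs)):
        seed = build_seed(net, drug, weights, strategy)
        try:
            res = propagate(tm, seed, r=r, tol=tol, max_iter=max_iter)
        except ConvergenceError as exc:
            logger.warning("propagation failed for drug %r: %s", drug, exc)
            failed.append(drug)
            continue
        u_inf, _, _ = res.blocks()
        scores[drug] = dict(zip(net.diseases, u_inf.tolist()))
    return scores, failed


def _rank_validation(
    scores: dict[str, dict[str, float]],
    validation: ValidationSet,
    disease_universe: tuple[str, ...],
    known: dict[str, set[str]],
    n_decoys: int,
    repetitions: int,
    rng: np.random.Generator,
    tie_break: str = "midrank",
) -> tuple[AucSummary, list[RankingRecord]]:
    """Shared decoy-draw / rank / average machinery for evaluate and baseline."""
    universe = np.asarray(disease_universe, dtype=object)
    records: list[RankingRecord] = []
    per_rep: list[float] = []
    skipped: list[tuple[str, str]] = []
    pairs = list(zip(validation.pairs["drug_id"], validation.pairs["disease_id"]))
    for rep in range(1, repetitions + 1):
        rep_ranks: list[float] = []
        for drug, disease in pairs:
            if drug not in scores:
                if rep == 1:
                    skipped.append((drug, disease))
                continue
            excluded = known.get(drug, set()) | {disease}
            pool = universe[~np.isin(universe, sorted(excluded))]
            if pool.size < n_decoys:
                raise ValueError(
                    f"only {pool.size} eligible decoys for pair ({drug!r}, {disease!r}); "
                    f"{n_decoys} required"
                )
            decoys = rng.choice(pool, size=n_decoys, replace=False)
            rank = rank_pair(scores[drug], disease, list(decoys), tie_break=tie_break)
            rep_ranks.append(rank)
            records.append(
                RankingRecord(drug, disease, rank, repetition=rep, n_decoys=n_decoys)
            )
        if not rep_ranks:
            raise ValueError("no validation pair could be ranked (all drugs unscorable)")
        per_rep.append(ranking_auc(rep_ranks, n_decoys=n_decoys).auc)
    if skipped:
        logger.warning("%d validation pairs skipped (unscorable drugs)", len(skipped))
    all_ranks = [rec.rank for rec in records]
    summary = ranking_auc(all_ranks, n_decoys=n_decoys)
    return (
        AucSummary(
            auc=float(np.mean(per_rep)),
            per_repetition=per_rep,
            curve=summary.curve,
            n_pairs=len(pairs) - len(skipped),
            skipped=skipped,
        ),
        records,
    )


def evaluate(
    net: HeteroNetwork,
    tm: TransitionMatrix,
    validation: ValidationSet,
    weights: LayerWeights | None = None,
    r: float = 0.7,
    repetitions: int = DEFAULT_REPETITIONS,
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int | None = None,
    tol: float = 1e-10,
    return_records: bool = False,
):
    """Decoy-ranking evaluation of the model on a validation set.

    Each repetition redraws the decoy lists (without replacement, never
    including a disease known to be linked to the drug); the reported AUC is
    the mean over repetitions. Pairs whose drug cannot be scored (absent from
    the network or diverging) are skipped with a warning and counted.
    """
    weights = weights or tm.weights
    rng = np.random.default_rng(seed)
    drugs = set(validation.pairs["drug_id"]) & set(net.drugs)
    missing = set(validation.pairs["drug_id"]) - drugs
    if missing:
        logger.warning("%d validation drugs absent from the network", len(missing))
    scores, _ = score_drugs(net, tm, drugs, weights, r=r, tol=tol)
    summary, records = _rank_validation(
        scores, validation, net.diseases, validation.known_diseases(),
        n_decoys, repetitions, rng,
    )
    return (summary, records) if return_records else summary


def random_baseline(
    net: HeteroNetwork,
    tm: TransitionMatrix,
    validation: ValidationSet,
    weights: LayerWeights | None = None,
    r: float = 0.7,
    repetitions: int = DEFAULT_REPETITIONS,
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int | None = None,
    tol: float = 1e-10,
):
    """Evaluation on a random set: validation diseases replaced by uniform draws.

    Each pair keeps its drug but the disease is drawn uniformly from the
    disease universe excluding the drug's known diseases, then the standard
    evaluation pipeline is applied. The expected AUC is 50%.
    """
    weights = weights or tm.weights
    rng = np.random.default_rng(seed)
    known = validation.known_diseases()
    universe = np.asarray(net.diseases, dtype=object)
    rows = []
    seen: set[tuple[str, str]] = set()
    for g in validation.pairs["drug_id"]:
        pool = universe[~np.isin(universe, sorted(known.get(g, set())))]
        d = str(rng.choice(pool))
        while (g, d) in seen:  # keep pairs unique, as in the validation set
            d = str(rng.choice(pool))
        seen.add((g, d))
        rows.append((g, d))
    randomized = ValidationSet(pd.DataFrame(rows, columns=["drug_id", "disease_id"]))
    drugs = set(randomized.pairs["drug_id"]) & set(net.drugs)
    scores, _ = score_drugs(net, tm, drugs, weights, r=r, tol=tol)
    summary, _ = _rank_validation(
        scores, randomized, net.diseases, known, n_decoys, repetitions, rng,
    )
    return summary


def cross_validate(
    net: HeteroNetwork,
    validation: ValidationSet,
    weights: LayerWeights | None = None,
    r: float = 0.7,
    folds: int = 10,
    repetitions: int = DEFAULT_REPETITIONS,
    n_decoys: int = DEFAULT_N_DECOYS,
    seed: int | None = None,
    tol: float = 1e-10,
) -> tuple[AucSummary, list[AucSummary]]:
    """K-fold cross-validation of the full (prior-knowledge) model.

    The validation pairs are split into folds; for each fold the held-out
    links are removed from S6, the transition matrix and seeds are rebuilt on
    the reduced prior, and the held-out pairs are evaluated. A drug whose
    prior links all fall in the held-out fold simply seeds without a disease
    block (logged), exactly as a never-seen drug would. Returns the pooled
    summary (mean of fold AUCs) and the per-fold summaries.
    """
    if net.S6.nnz == 0:
        raise ValueError("cross-validation requires the full strategy (non-empty S6)")
    weights = weights or LayerWeights()
    rng = np.random.default_rng(seed)
    folded = validation.assign_folds(folds, rng)
    fold_summaries: list[AucSummary] = []
    known = validation.known_diseases()
    for k in range(1, folds + 1):
        held = folded.pairs[folded.pairs["fold"] == k]
        if held.empty:
            continue
        s6 = net.S6.tolil(copy=True)
        for g, d in zip(held["drug_id"], held["disease_id"]):
            if g in net.drugs and d in net.diseases:
                s6[net.drug_pos(g), net.disease_pos(d)] = 0.0
        fold_net = net.with_s6(s6.tocsr())
        fold_tm = build_transition(fold_net, strategy="full", weights=weights)
        fold_val = ValidationSet(held.reset_index(drop=True))
        drugs = set(held["drug_id"]) & set(net.drugs)
        scores, _ = score_drugs(fold_net, fold_tm, drugs, weights, r=r, tol=tol)
        summary, _ = _rank_validation(
            scores, fold_val, net.diseases, known, n_decoys, repetitions,
            np.random.default_rng(rng.integers(2**31)),
        )
        fold_summaries.append(summary)
    mean_auc = float(np.mean([s.auc for s in fold_summaries]))
    pooled = AucSummary(
        auc=mean_auc,
        per_repetition=[s.auc for s in fold_summaries],
        n_pairs=sum(s.n_pairs for s in fold_summaries),
    )
    return pooled, fold_summaries
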