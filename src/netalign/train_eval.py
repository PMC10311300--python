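"""Training, fine-tuning, and evaluation (AUROC / AUPRC / top-k Jaccard
function transfer).

Training is full-batch Adam on binary cross-entropy over the train
PairSet, with early stopping on validation AUPRC; the selected model is
the epoch with the best validation AUPRC.  Function transfer ranks all
candidate cross-species pairs among annotated proteins, takes the top k
by score, and summarises the Jaccard index between the two proteins'
term sets, against a random-pair baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from . import autodiff as ad
from .gnn_model import AlignerModel, GraphFeatures, ModelConfig
from .network_io import AnnotationTable, ValidationError
from .sampling import PairSet

logger = logging.getLogger(__name__)


@dataclass
class TrainReport:
    train_loss: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    valid_auprc: list[float] = field(default_factory=list)
    selected_epoch: int = -1
    seed: int = 0
    config_hash: str = ""


@dataclass
class EvalReport:
    auroc: float
    auprc: float
    n_pos: int
    n_neg: int
    jaccard_summary: dict | None = None


def _config_hash(config: ModelConfig) -> str:
    import hashlib
    from dataclasses import asdict

    return hashlib.sha256(repr(sorted(asdict(config).items()))
                          .encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epoch_loss(model: AlignerModel, feats: GraphFeatures,
                i_idx, j_idx, labels, train: bool,
                rng: np.random.Generator | None) -> ad.Tensor:
    h = model.forward(feats, train=train, rng=rng)
    logits = model.pair_logits(h, i_idx, j_idx, train=train, rng=rng)
    return ad.bce_with_logits(logits, labels.reshape(-1, 1))


def train(jg, feats: GraphFeatures, pairsets: dict[str, PairSet],
          config: ModelConfig,
          resampler=None) -> tuple[AlignerModel, TrainReport]:
    """Train from scratch; model selected at best validation AUPRC.

    ``resampler``, if given (see ``sampling.negative_resampler``), draws
    a fresh training-negative set every epoch instead of keeping the
    frozen default.
    """
    model = AlignerModel(config, jg.n1, jg.n2)
    opt = ad.Adam(model.params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    report = TrainReport(seed=config.seed, config_hash=_config_hash(config))

    tr_pairs, tr_labels = pairsets["train"].as_arrays()
    va_pairs, va_labels = pairsets["valid"].as_arrays()
    tr_i, tr_j = model.pair_indices(jg, tr_pairs)
    va_i, va_j = model.pair_indices(jg, va_pairs)

    best_auprc = -np.inf
    best_params = None
    best_epoch = -1
    stale = 0
    for epoch in range(config.max_epochs):
        if resampler is not None and epoch > 0:
            neg = resampler((config.seed * 1009 + epoch) % (2 ** 31))
            fresh = PairSet(pairsets["train"].positives, neg,
                            pairsets["train"].sampling_mode, config.seed)
            tr_pairs, tr_labels = fresh.as_arrays()
            tr_i, tr_j = model.pair_indices(jg, tr_pairs)
        opt.zero_grad()
        loss = _epoch_loss(model, feats, tr_i, tr_j, tr_labels, True, rng)
        if not np.isfinite(loss.v):
            raise RuntimeError(
                f"training diverged (loss={loss.v!r}) at epoch {epoch}; "
                "reduce the learning rate or check the input features")
        loss.backward()
        opt.step()
        report.train_loss.append(float(loss.v))

        h = model.forward(feats, train=False)
        va_logits = model.pair_logits(h, va_i, va_j)
        va_scores = ad.sigmoid(va_logits).v.ravel()
        report.valid_loss.append(
            float(ad.bce_with_logits(va_logits,
                                     va_labels.reshape(-1, 1)).v))
        auprc = float(average_precision_score(va_labels, va_scores))
        report.valid_auprc.append(auprc)
        if auprc > best_auprc:
            best_auprc = auprc
            best_epoch = epoch
            best_params = {k: p.v.copy() for k, p in model.params.items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    for k, v in best_params.items():
        model.params[k].v = v
    report.selected_epoch = best_epoch
    logger.info("selected epoch %d (valid AUPRC %.4f) after %d epochs",
                best_epoch, best_auprc, len(report.train_loss))
    return model, report


def finetune(model: AlignerModel, jg, feats: GraphFeatures,
             new_pairs: PairSet, freeze_gnn: bool = True,
             epochs: int = 100, lr: float = 1e-3,
             seed: int = 0) -> AlignerModel:
    """Re-train on new labels; with ``freeze_gnn`` only the MLP head
    changes and all block/projection parameters stay bit-identical."""
    tuned = model.copy()
    if freeze_gnn:
        trainable = {k: tuned.params[k] for k in tuned.head_param_names()}
    else:
        trainable = tuned.params
    opt = ad.Adam(trainable, lr=lr)
    rng = np.random.default_rng(seed)
    pairs, labels = new_pairs.as_arrays()
    i_idx, j_idx = tuned.pair_indices(jg, pairs)
    # frozen embeddings are detached so backprop stops at the head
    h_frozen = (ad.Tensor(tuned.forward(feats, train=False).v)
                if freeze_gnn else None)
    for _ in range(epochs):
        opt.zero_grad()
        h = h_frozen if freeze_gnn else tuned.forward(feats, train=True,
                                                      rng=rng)
        logits = tuned.pair_logits(h, i_idx, j_idx)
        loss = ad.bce_with_logits(logits, labels.reshape(-1, 1))
        loss.backward()
        opt.step()
    return tuned


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_ranking(model: AlignerModel, jg, feats: GraphFeatures,
                     test_pairs: PairSet) -> EvalReport:
    """AUROC and AUPRC of the model's scores on a labelled pair set."""
    pairs, labels = test_pairs.as_arrays()
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("evaluation needs both labels present")
    scores = model.score_pairs(feats, pairs)
    return EvalReport(auroc=float(roc_auc_score(labels, scores)),
                      auprc=float(average_precision_score(labels, scores)),
                      n_pos=n_pos, n_neg=n_neg)


def jaccard_index(terms1: set, terms2: set) -> float:
    union = terms1 | terms2
    if not union:
        return 0.0
    return len(terms1 & terms2) / len(union)


def evaluate_function_transfer(model: AlignerModel, jg,
                               feats: GraphFeatures, ann1: AnnotationTable,
                               ann2: AnnotationTable, k: int = 5000,
                               seed: int = 0, batch: int = 200_000,
                               candidate_cap: int = 5_000_000) -> dict:
    """Top-k Jaccard function-transfer evaluation.

    Candidates are all cross pairs among PPI-present proteins with at
    least one term (capped at ``candidate_cap``, scored in batches); the
    top k by score (ties broken by canonical node-id order) give the
    model's Jaccard distribution, compared with ``k`` random candidate
    pairs.  Returns per-pair values plus summary statistics.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    prot1 = [p for p in ann1.annotated_proteins() if p in jg.g1.index]
    prot2 = [q for q in ann2.annotated_proteins() if q in jg.g2.index]
    n_cand = len(prot1) * len(prot2)
    if n_cand > candidate_cap:
        raise ValidationError("candidate universe exceeds the configured cap")
    if n_cand < k:
        logger.warning("only %d candidates for top-%d; using all", n_cand, k)
        k = n_cand
    h = model.forward(feats, train=False)
    all_pairs: list[tuple[str, str]] = [(p, q) for p in prot1 for q in prot2]
    scores = np.empty(n_cand)
    for start in range(0, n_cand, batch):
        chunk = all_pairs[start:start + batch]
        scores[start:start + len(chunk)] = model.score_pairs(
            feats, chunk, h=h)
    # sort by descending score, ties by canonical pair order
    order = sorted(range(n_cand), key=lambda i: (-scores[i], all_pairs[i]))
    top = [all_pairs[i] for i in order[:k]]
    top_j = np.array([jaccard_index(ann1.terms(p), ann2.terms(q))
                      for p, q in top])
    rng = np.random.default_rng(seed)
    rand_idx = rng.choice(n_cand, size=k, replace=False)
    rand_j = np.array([jaccard_index(ann1.terms(all_pairs[i][0]),
                                     ann2.terms(all_pairs[i][1]))
                       for i in rand_idx])
    summary = {
        "k": int(k),
        "model_mean": float(top_j.mean()),
        "model_median": float(np.median(top_j)),
        "random_mean": float(rand_j.mean()),
        "random_median": float(np.median(rand_j)),
        "tie_break": "descending score, then canonical node-id order",
    }
    return {"model_jaccard": top_j, "random_jaccard": rand_j,
            "top_pairs": top, "summary": summary}
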