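"""Multi-objective encoder pretraining with a dual corrupted/clean pass.

Each batch is processed twice: once with a fraction of non-special tokens
replaced by the mask token (the corrupted pass, feeding the masking head)
and once untouched (the clean pass, whose pooled vector feeds the
physicochemical-regression and in vitro-assay heads).  The training loss
is the arithmetic mean of the enabled head losses; the in vitro head uses
the weighted focal loss with alpha = 1, gamma = 2 held fixed.

Head configurations mirror the three encoder modes:

==================  ====  ========  =======
mode                mask  physchem  invitro
==================  ====  ========  =======
mask+physchem        x       x
vitro (full)         x       x         x
==================  ====  ========  =======
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import chem
from .chem import Molecule, TokenSequence, Vocab
from .evaluation import aupr
from .labels import SparseLabelMatrix
from .nn import Adam, EncoderConfig, Linear, Module, TransformerEncoder, linear_warmup
from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import LayerNorm
from .nn.transformer import EncoderLayer

INVITRO_ALPHA = 1.0  # fixed for in vitro pretraining
INVITRO_GAMMA = 2.0


# ---------------------------------------------------------------------------
# Batching and corruption
# ---------------------------------------------------------------------------


def collate(
    seqs: list[TokenSequence], vocab: Vocab, max_length: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pad token sequences into (B, T) ids plus a 0/1 pad mask."""
    longest = max(s.length for s in seqs)
    if longest > max_length:
        raise ValueError(f"batch contains a sequence of length {longest} > {max_length}")
    ids = np.full((len(seqs), longest), vocab.pad_id, dtype=np.int64)
    pad_mask = np.zeros((len(seqs), longest), dtype=np.int64)
    for i, s in enumerate(seqs):
        ids[i, : s.length] = s.ids
        pad_mask[i, : s.length] = 1
    return ids, pad_mask


@dataclass
class CorruptionResult:
    """A corrupted token array with its mask indicators."""

    corrupted: np.ndarray  # same shape as the input ids
    mask: np.ndarray  # bool, True where the token was masked
    originals: np.ndarray  # the original ids (untouched copy)

    @property
    def n_masked(self) -> int:
        return int(self.mask.sum())


def corrupt_batch(
    ids: np.ndarray,
    vocab: Vocab,
    mask_rate: float,
    rng: np.random.Generator,
    policy: str = "mask",
) -> CorruptionResult:
    """Independently mask each non-special position with ``mask_rate``.

    The default policy replaces every selected token by the mask token;
    ``policy="bert"`` applies the conventional 80/10/10
    mask/random/keep split instead.  Special tokens (begin/end/pad) are
    never selected.  Deterministic under a fixed generator state.
    """
    if not 0.0 <= mask_rate < 1.0:
        raise ValueError("mask_rate must lie in [0, 1)")
    if policy not in ("mask", "bert"):
        raise ValueError("policy must be 'mask' or 'bert'")
    ids = np.asarray(ids, dtype=np.int64)
    special = np.isin(ids, list(vocab.special_ids))
    selected = (rng.random(ids.shape) < mask_rate) & ~special
    corrupted = ids.copy()
    if policy == "mask":
        corrupted[selected] = vocab.mask_id
    else:
        u = rng.random(ids.shape)
        replace_mask = selected & (u < 0.8)
        replace_rand = selected & (u >= 0.8) & (u < 0.9)
        corrupted[replace_mask] = vocab.mask_id
        n_specials = len(vocab.SPECIALS)
        corrupted[replace_rand] = rng.integers(
            n_specials, len(vocab), size=int(replace_rand.sum())
        )
    return CorruptionResult(corrupted=corrupted, mask=selected, originals=ids)


def corrupt(
    seq: TokenSequence,
    vocab: Vocab,
    mask_rate: float,
    rng: np.random.Generator,
    policy: str = "mask",
) -> CorruptionResult:
    """Single-sequence convenience wrapper around :func:`corrupt_batch`."""
    return corrupt_batch(seq.ids[None, :], vocab, mask_rate, rng, policy)


# ---------------------------------------------------------------------------
# Heads and the full pretraining model
# ---------------------------------------------------------------------------


class MLPHead(Module):
    """One-hidden-layer head reading the pooled clean embedding."""

    def __init__(self, hidden: int, width: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(hidden, width, rng)
        self.fc2 = Linear(width, n_out, rng)

    def __call__(self, pooled: Tensor) -> Tensor:
        return self.fc2(ag.relu(self.fc1(pooled)))


class MaskingHead(Module):
    """Linear -> GELU + layer norm -> one encoder layer -> vocabulary logits."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.proj = Linear(config.hidden, config.hidden, rng)
        self.ln = LayerNorm(config.hidden)
        self.block = EncoderLayer(config.hidden, config.n_heads, config.ffn, rng)
        self.vocab_proj = Linear(config.hidden, config.vocab_size, rng)

    def __call__(self, hidden: Tensor, pad_mask: np.ndarray,
                 drop_rate: float, rng: np.random.Generator) -> Tensor:
        x = self.ln(ag.gelu(self.proj(hidden)))
        x = self.block(x, pad_mask, drop_rate, rng)
        return self.vocab_proj(x)


@dataclass
class HeadConfig:
    """Which heads contribute to the pretraining loss (see module table)."""

    mask: bool = True
    physchem: bool = True
    invitro: bool = True
    head_width: int | None = None  # defaults to the encoder hidden size

    def __post_init__(self) -> None:
        if not (self.mask or self.physchem or self.invitro):
            raise ValueError("at least one head must be enabled")


@dataclass
class HeadOutputs:
    """Outputs of one dual pass.

    Masking logits come from the corrupted pass only; physchem estimates
    and in vitro logits from the clean pass only.
    """

    masking_logits: Tensor | None
    physchem: Tensor | None
    invitro: Tensor | None
    corruption: CorruptionResult | None


class PretrainModel(Module):
    """Shared encoder plus masking / physchem / in vitro heads."""

    def __init__(
        self,
        encoder_config: EncoderConfig,
        n_physchem: int,
        n_invitro: int,
        heads: HeadConfig | None = None,
    ):
        super().__init__()
        self.encoder_config = encoder_config
        self.heads = heads or HeadConfig()
        self.n_physchem = n_physchem
        self.n_invitro = n_invitro
        rng = np.random.default_rng(encoder_config.seed + 1)
        self.encoder = TransformerEncoder(encoder_config)
        width = self.heads.head_width or encoder_config.hidden
        self.masking_head = MaskingHead(encoder_config, rng) if self.heads.mask else None
        self.physchem_head = (
            MLPHead(encoder_config.hidden, width, n_physchem, rng)
            if self.heads.physchem else None
        )
        self.invitro_head = (
            MLPHead(encoder_config.hidden, width, n_invitro, rng)
            if self.heads.invitro else None
        )

    def dual_pass(
        self,
        ids: np.ndarray,
        pad_mask: np.ndarray,
        vocab: Vocab,
        mask_rate: float,
        rng: np.random.Generator,
        policy: str = "mask",
    ) -> HeadOutputs:
        """Corrupted pass for the masking head, clean pass for the others."""
        corruption = None
        masking_logits = None
        if self.masking_head is not None:
            corruption = corrupt_batch(ids, vocab, mask_rate, rng, policy)
            h_corr = self.encoder(corruption.corrupted, pad_mask, rng)
            masking_logits = self.masking_head(
                h_corr, pad_mask, self.encoder_config.dropout, rng
            )
        physchem = invitro = None
        if self.physchem_head is not None or self.invitro_head is not None:
            h_clean = self.encoder(ids, pad_mask, rng)
            pooled = self.encoder.pooled(h_clean, pad_mask)
            if self.physchem_head is not None:
                physchem = self.physchem_head(pooled)
            if self.invitro_head is not None:
                invitro = self.invitro_head(pooled)
        return HeadOutputs(masking_logits, physchem, invitro, corruption)


# ---------------------------------------------------------------------------
# Differentiable losses on head outputs
# ---------------------------------------------------------------------------


def focal_loss_tensor(
    logits: Tensor,
    labels: np.ndarray,
    weights: np.ndarray,
    gamma: float,
) -> Tensor:
    """Weighted focal loss as a differentiable graph node.

    ``labels`` may contain NaN (missing); such entries contribute neither
    loss nor gradient.  ``weights`` holds w+_p per task.
    """
    labels = np.asarray(labels, dtype=np.float64)
    obs = ~np.isnan(labels)
    n_obs = int(obs.sum())
    if n_obs == 0:
        raise ValueError("all labels missing in batch")
    pos = (obs & (labels == 1.0)).astype(np.float64)
    neg = (obs & (labels == 0.0)).astype(np.float64)
    w = np.asarray(weights, dtype=np.float64)[None, :]
    s = ag.sigmoid(logits)
    nll_pos = ag.mul(ag.log_sigmoid(logits), -1.0)
    nll_neg = ag.mul(ag.log_sigmoid(ag.mul(logits, -1.0)), -1.0)
    if gamma == 0.0:
        focal_pos, focal_neg = 1.0, 1.0
        term_pos = ag.mul(nll_pos, pos * w)
        term_neg = ag.mul(nll_neg, neg)
    else:
        focal_pos = ag.power(1.0 - s, gamma)
        focal_neg = ag.power(s, gamma)
        term_pos = ag.mul(ag.mul(focal_pos, nll_pos), pos * w)
        term_neg = ag.mul(ag.mul(focal_neg, nll_neg), neg)
    total = ag.sum_all(term_pos + term_neg)
    return ag.mul(total, 1.0 / n_obs)


def mse_loss_tensor(estimates: Tensor, targets: np.ndarray) -> Tensor:
    """Mean over samples of squared Euclidean error across properties."""
    diff = estimates - np.asarray(targets, dtype=np.float64)
    n = estimates.shape[0]
    return ag.mul(ag.sum_all(ag.mul(diff, diff)), 1.0 / n)


def combined_loss(
    outs: HeadOutputs,
    physchem_targets: np.ndarray | None,
    invitro_labels: np.ndarray | None,
    invitro_weights: np.ndarray | None,
) -> tuple[Tensor, dict[str, float]]:
    """Arithmetic mean of the enabled head losses, plus per-head components."""
    components: dict[str, float] = {}
    terms: list[Tensor] = []
    if outs.masking_logits is not None:
        if outs.corruption is None or outs.corruption.n_masked == 0:
            components["masking"] = 0.0  # degenerate batch: nothing was masked
        else:
            lm = ag.masked_cross_entropy(
                outs.masking_logits, outs.corruption.originals, outs.corruption.mask
            )
            components["masking"] = lm.item()
            terms.append(lm)
    if outs.physchem is not None:
        lp = mse_loss_tensor(outs.physchem, physchem_targets)
        components["physchem"] = lp.item()
        terms.append(lp)
    if outs.invitro is not None:
        li = focal_loss_tensor(
            outs.invitro, invitro_labels, invitro_weights, INVITRO_GAMMA
        )
        components["invitro"] = li.item()
        terms.append(li)
    if not terms:
        raise ValueError("no head produced a loss")
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    total = ag.mul(total, 1.0 / len(terms))
    components["total"] = total.item()
    return total, components


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class PretrainConfig:
    """Schedule and corruption settings for encoder pretraining."""

    epochs: int = 10
    batch_size: int = 32
    lr: float = 3e-5
    warmup_frac: float = 0.01
    mask_rate: float = 0.15
    masking_policy: str = "mask"
    weight_decay: float = 0.0
    val_fraction_folds: int = 5  # scaffold folds; one is held out for validation
    seed: int = 0


@dataclass
class PretrainData:
    """Aligned pretraining corpus: molecules, descriptor targets, assay labels."""

    molecules: list[Molecule]
    physchem_targets: np.ndarray | None  # N x D, already normalized
    invitro: SparseLabelMatrix | None

    def __post_init__(self) -> None:
        n = len(self.molecules)
        if self.physchem_targets is not None and self.physchem_targets.shape[0] != n:
            raise ValueError("physchem targets misaligned with molecules")
        if self.invitro is not None and self.invitro.n_molecules != n:
            raise ValueError("in vitro labels misaligned with molecules")


@dataclass
class PretrainResult:
    model: PretrainModel
    vocab: Vocab
    history: list[dict]
    train_indices: np.ndarray
    val_indices: np.ndarray


def _length_batches(
    indices: np.ndarray,
    seqs: list[TokenSequence],
    batch_size: int,
    rng: np.random.Generator | None,
) -> list[np.ndarray]:
    """Batches bucketed by sequence length to minimize padding waste.

    With an rng, ties are shuffled and the batch order is randomized (for
    training); without one the grouping is deterministic (for eval).
    """
    idx = np.asarray(indices)
    lengths = np.array([seqs[i].length for i in idx])
    tiebreak = rng.random(idx.size) if rng is not None else np.zeros(idx.size)
    order = idx[np.lexsort((tiebreak, lengths))]
    batches = [order[s : s + batch_size] for s in range(0, len(order), batch_size)]
    if rng is not None:
        batches = [batches[i] for i in rng.permutation(len(batches))]
    return batches


def _eval_epoch(
    model: PretrainModel,
    vocab: Vocab,
    seqs: list[TokenSequence],
    idx: np.ndarray,
    data: PretrainData,
    cfg: PretrainConfig,
    batch_size: int,
) -> dict:
    """Validation metrics: physchem loss, masked-token accuracy, in vitro AUPR."""
    model.eval()
    rng = np.random.default_rng(cfg.seed + 9999)  # fixed mask pattern across epochs
    n_correct = n_masked = 0
    physchem_sse, physchem_n = 0.0, 0
    invitro_rows: list[np.ndarray] = []
    invitro_logits: list[np.ndarray] = []
    for rows in _length_batches(idx, seqs, batch_size, None):
        ids, pad_mask = collate([seqs[i] for i in rows], vocab, model.encoder_config.max_length)
        outs = model.dual_pass(ids, pad_mask, vocab, cfg.mask_rate, rng, cfg.masking_policy)
        if outs.masking_logits is not None and outs.corruption.n_masked > 0:
            pred = outs.masking_logits.data.argmax(axis=-1)
            m = outs.corruption.mask
            n_correct += int((pred[m] == outs.corruption.originals[m]).sum())
            n_masked += int(m.sum())
        if outs.physchem is not None:
            diff = outs.physchem.data - data.physchem_targets[rows]
            physchem_sse += float((diff**2).sum())
            physchem_n += len(rows)
        if outs.invitro is not None:
            invitro_rows.append(rows)
            invitro_logits.append(outs.invitro.data)
    record: dict = {}
    if n_masked:
        record["val_mask_accuracy"] = n_correct / n_masked
    if physchem_n:
        record["val_physchem_loss"] = physchem_sse / physchem_n
    if invitro_logits and data.invitro is not None:
        logits = np.concatenate(invitro_logits, axis=0)
        labels = data.invitro.values[np.concatenate(invitro_rows)]
        auprs = []
        for j in range(labels.shape[1]):
            obs = ~np.isnan(labels[:, j])
            yj = labels[obs, j]
            if yj.size and 0 < yj.sum() < yj.size:
                auprs.append(aupr(yj, logits[obs, j]))
        if auprs:
            record["val_invitro_aupr"] = float(np.mean(auprs))
    model.train()
    return record


def fit_pretrain(
    data: PretrainData,
    encoder_config: EncoderConfig,
    cfg: PretrainConfig | None = None,
    heads: HeadConfig | None = None,
    vocab: Vocab | None = None,
) -> PretrainResult:
    """Train the encoder with the enabled heads on a molecule corpus.

    A scaffold-disjoint validation fold is reserved before training; the
    history records the per-epoch validation triplet (physchem loss,
    masked-token accuracy, in vitro AUPR).  Divergence (non-finite loss)
    aborts with a diagnostic.
    """
    cfg = cfg or PretrainConfig()
    heads = heads or HeadConfig()
    vocab = vocab or Vocab.from_corpus(data.molecules)
    if encoder_config.vocab_size != len(vocab):
        raise ValueError(
            f"encoder vocab_size {encoder_config.vocab_size} != vocabulary size {len(vocab)}"
        )
    if heads.invitro and data.invitro is None:
        raise ValueError("in vitro head enabled but no in vitro labels supplied")
    if heads.physchem and data.physchem_targets is None:
        raise ValueError("physchem head enabled but no descriptor targets supplied")

    seqs = [
        chem.tokenize(m, vocab, encoder_config.max_length) for m in data.molecules
    ]
    split = chem.scaffold_split(data.molecules, cfg.val_fraction_folds, cfg.seed)
    val_idx = split.test_indices()
    train_idx = split.train_indices()

    n_physchem = data.physchem_targets.shape[1] if data.physchem_targets is not None else 0
    n_invitro = data.invitro.n_tasks if data.invitro is not None else 0
    model = PretrainModel(encoder_config, n_physchem, n_invitro, heads)

    weights = None
    if heads.invitro:
        train_labels = data.invitro.values[train_idx]
        obs = ~np.isnan(train_labels)
        n_pos = np.nansum(train_labels, axis=0)
        n_neg = obs.sum(axis=0) - n_pos
        weights = np.ones(n_invitro)
        ok = n_pos > 0
        weights[ok] = INVITRO_ALPHA * n_neg[ok] / n_pos[ok] + (1 - INVITRO_ALPHA)

    params = model.parameters()
    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = max(1, int(np.ceil(len(train_idx) / cfg.batch_size)))
    total_steps = steps_per_epoch * cfg.epochs
    history: list[dict] = []
    step = 0
    for epoch in range(cfg.epochs):
        epoch_components: dict[str, list[float]] = {}
        for rows in _length_batches(train_idx, seqs, cfg.batch_size, rng):
            ids, pad_mask = collate([seqs[i] for i in rows], vocab, encoder_config.max_length)
            outs = model.dual_pass(ids, pad_mask, vocab, cfg.mask_rate, rng, cfg.masking_policy)
            loss, components = combined_loss(
                outs,
                data.physchem_targets[rows] if heads.physchem else None,
                data.invitro.values[rows] if heads.invitro else None,
                weights,
            )
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, step {step}: "
                    f"loss components {components}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step(lr_scale=linear_warmup(step, total_steps, cfg.warmup_frac))
            step += 1
            for key, value in components.items():
                epoch_components.setdefault(key, []).append(value)
        record = {"epoch": epoch}
        record.update({f"train_{k}": float(np.mean(v)) for k, v in epoch_components.items()})
        record.update(
            _eval_epoch(model, vocab, seqs, val_idx, data, cfg, cfg.batch_size)
        )
        history.append(record)
    return PretrainResult(model, vocab, history, train_idx, val_idx)


# ---------------------------------------------------------------------------
# Checkpoints (config + vocabulary embedded, so they are self-describing)
# ---------------------------------------------------------------------------


def save_checkpoint(result: PretrainResult | "PretrainModel", path: str | Path,
                    vocab: Vocab | None = None) -> None:
    if isinstance(result, PretrainResult):
        model, vocab = result.model, result.vocab
    else:
        model = result
        if vocab is None:
            raise ValueError("vocab required when saving a bare model")
    meta = {
        "encoder_config": model.encoder_config.to_dict(),
        "heads": {
            "mask": model.masking_head is not None,
            "physchem": model.physchem_head is not None,
            "invitro": model.invitro_head is not None,
            "head_width": model.heads.head_width,
        },
        "n_physchem": model.n_physchem,
        "n_invitro": model.n_invitro,
        "vocab": vocab.tokens,
    }
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str | Path) -> tuple[PretrainModel, Vocab]:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(bytes(archive["__meta__"]).decode())
    config = EncoderConfig(**meta["encoder_config"])
    heads = HeadConfig(**meta["heads"])
    model = PretrainModel(config, meta["n_physchem"], meta["n_invitro"], heads)
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
    vocab = Vocab(meta["vocab"])
    return model, vocab
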