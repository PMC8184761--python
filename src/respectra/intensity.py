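"""Recurrent fragment-intensity predictor, its loss/schedule, data hygiene
and collision-energy calibration.

The network is an encoder-decoder: a 3-layer peptide encoder (bidirectional
GRU, GRU, additive attention pooling, dropout), a single dense metadata
encoder for precursor charge (one-hot, 6) and NCE (scaled to [0, 1]), fusion
by element-wise multiplication, and a length-29 bidirectional GRU decoder
with attention emitting 6 intensities (b/y x charge 1..3) per position.
Training minimises 1 - spectral angle on the masked 174-dim target with an
Adam optimizer under a triangular cyclic learning rate.

Desk-scale defaults (64 recurrent units) keep single-CPU training in
minutes; the architecture accepts the publication-scale 512 units through
the same configuration.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nn
from .annotation import FLAT_DIM, FragmentMatrix, mask_array
from .chem import MAX_LENGTH, MAX_PRECURSOR_CHARGE, Peptide

_PAD = 0
_TOKENS = {ch: i + 1 for i, ch in enumerate("ACDEFGHIKLMNPQRSTVWY")}
_TOKENS["M(ox)"] = 21
_TOKENS["C(cam)"] = 22
VOCAB_SIZE = 23
_MOD_TOKEN = re.compile(r"[A-Z](?:\(\w+\))?")
_STRIP_MODS = re.compile(r"\(\w+\)")


def tokenize(modified_sequence: str) -> list[int]:
    return [_TOKENS[tok] for tok in _MOD_TOKEN.findall(modified_sequence)]


def unmodified(sequence: str) -> str:
    return _STRIP_MODS.sub("", sequence)


@dataclass
class TrainConfig:
    """Optimisation settings: cyclic learning rate limits, decay, batching."""

    clr_low: float = 1e-7
    clr_high0: float = 1e-3
    clr_decay: float = 0.95
    decay_every: int = 8          # epochs between decays of the upper limit
    half_cycle: float = 4.0       # epochs from trough to peak (triangular)
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 10
    steps_per_epoch: int = 1
    seed: int = 0
    # optional fine-tuning restart: from ``restart_epoch`` on, the cycle
    # restarts with the (lower) upper limit ``restart_high``
    restart_epoch: int | None = None
    restart_high: float = 1e-4


def clr_high(epoch: int, cfg: TrainConfig) -> float:
    """Current upper limit: initial high scaled by decay every ``decay_every`` epochs."""
    if cfg.restart_epoch is not None and epoch >= cfg.restart_epoch:
        epoch = epoch - cfg.restart_epoch
        high0 = cfg.restart_high
    else:
        high0 = cfg.clr_high0
    return high0 * cfg.clr_decay ** (epoch // cfg.decay_every)


def clr_schedule(step: int, epoch: int, cfg: TrainConfig) -> float:
    """Triangular cyclic learning rate between ``clr_low`` and the decayed high."""
    high = clr_high(epoch, cfg)
    if high <= cfg.clr_low:
        return cfg.clr_low
    if cfg.restart_epoch is not None and epoch >= cfg.restart_epoch:
        epoch = epoch - cfg.restart_epoch
    t = epoch + step / max(1, cfg.steps_per_epoch)
    pos = t % (2.0 * cfg.half_cycle)
    frac = pos / cfg.half_cycle if pos <= cfg.half_cycle else (2.0 * cfg.half_cycle - pos) / cfg.half_cycle
    return cfg.clr_low + (high - cfg.clr_low) * frac


def split_by_sequence(frame: pd.DataFrame, fractions=(0.70, 0.20, 0.10),
                      seed: int = 0, column: str = "modified_sequence"
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Sequence-disjoint train/test/holdout partition.

    The partition is by *unmodified* sequence: every PSM of a sequence lands
    in exactly one set.  Set sizes follow the fractions on unique sequences
    (within rounding).
    """
    if not math.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    sequences = frame[column].map(unmodified)
    unique = sorted(sequences.unique())
    if len(unique) < 3:
        raise ValueError("need at least 3 unique sequences to split")
    rng = np.random.default_rng(seed)
    rng.shuffle(unique)
    n = len(unique)
    n_train = round(fractions[0] * n)
    n_test = round(fractions[1] * n)
    groups = (set(unique[:n_train]), set(unique[n_train:n_train + n_test]),
              set(unique[n_train + n_test:]))
    parts = tuple(frame[sequences.isin(g)].copy() for g in groups)
    assert sum(len(p) for p in parts) == len(frame)
    return parts


def select_training_psms(frame: pd.DataFrame, k: int = 3,
                         score_col: str = "engine_score") -> pd.DataFrame:
    """Keep the top-``k`` scoring PSMs per acquisition-condition group.

    The group key is every column among (modified_sequence, precursor_charge,
    method, nce, analyzer) present in the table; ties break stably by
    (rawfile, scan).
    """
    keys = [c for c in ("modified_sequence", "precursor_charge", "method",
                        "nce", "analyzer") if c in frame.columns]
    sort_cols = [score_col] + [c for c in ("rawfile", "scan") if c in frame.columns]
    ordered = frame.sort_values(
        sort_cols, ascending=[False] + [True] * (len(sort_cols) - 1),
        kind="stable")
    return ordered.groupby(keys, sort=False).head(k)


def sa_loss(pred: np.ndarray, true: np.ndarray, mask: np.ndarray) -> float:
    """1 - spectral angle, masked dims excluded; 0 iff proportional."""
    tensor = nn.Tensor(np.atleast_2d(pred))
    loss = nn.masked_spectral_angle_loss(tensor, np.atleast_2d(true),
                                         np.atleast_2d(mask).astype(float))
    return float(loss.data)


def flat_spectral_angles(pred: np.ndarray, true: np.ndarray,
                         mask: np.ndarray) -> np.ndarray:
    """Per-row spectral angles between masked flat vectors (numpy only)."""
    p = np.where(mask, np.clip(pred, 0.0, None), 0.0)
    t = np.where(mask, np.clip(true, 0.0, None), 0.0)
    norm_p = np.linalg.norm(p, axis=1)
    norm_t = np.linalg.norm(t, axis=1)
    dot = (p * t).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = np.clip(dot / (norm_p * norm_t), -1.0, 1.0)
    sa = 1.0 - 2.0 * np.arccos(cosine) / np.pi
    return np.where((norm_p > 0) & (norm_t > 0), sa, 0.0)


def encode_frame(frame: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(tokens (n, 30), metadata (n, 7), mask (n, 174)) from a PSM frame."""
    n = len(frame)
    tokens = np.zeros((n, MAX_LENGTH), dtype=np.int64)
    meta = np.zeros((n, MAX_PRECURSOR_CHARGE + 1))
    masks = np.zeros((n, FLAT_DIM), dtype=bool)
    for i, row in enumerate(frame.itertuples(index=False)):
        toks = tokenize(row.modified_sequence)
        tokens[i, :len(toks)] = toks
        charge = int(row.precursor_charge)
        meta[i, charge - 1] = 1.0
        meta[i, MAX_PRECURSOR_CHARGE] = float(row.nce) / 100.0
        masks[i] = mask_array(len(toks), charge).reshape(FLAT_DIM)
    return tokens, meta, masks


class _IntensityNet:
    """The encoder-decoder graph; parameters live in nn.Tensor leaves."""

    def __init__(self, units: int, dec_units: int, embed_dim: int,
                 dropout: float, rng: np.random.Generator):
        self.units, self.dec_units = units, dec_units
        self.dropout = dropout
        self.embedding = nn.Tensor(rng.normal(0.0, 0.1, size=(VOCAB_SIZE, embed_dim)))
        self.enc_bigru = nn.BiGRU(rng, embed_dim, units)
        self.enc_gru = nn.GRUCell(rng, 2 * units, units)
        self.enc_attention = nn.AdditiveAttention(rng, units)
        self.meta_dense = nn.Dense(rng, MAX_PRECURSOR_CHARGE + 1, units)
        # learned positional embedding concatenated to the repeated latent so
        # the decoder need not count its 29 steps internally
        self.pos_dim = 8
        self.pos_embedding = nn.Tensor(rng.normal(0.0, 0.1, size=(29, self.pos_dim)))
        self.dec_bigru = nn.BiGRU(rng, units + self.pos_dim, dec_units)
        self.dec_attention = nn.AdditiveAttention(rng, 2 * dec_units)
        self.out_dense = nn.Dense(rng, 2 * dec_units, 6)

    def parameters(self) -> list[nn.Tensor]:
        return ([self.embedding, self.pos_embedding]
                + self.enc_bigru.parameters() + self.enc_gru.parameters()
                + self.enc_attention.parameters() + self.meta_dense.parameters()
                + self.dec_bigru.parameters() + self.dec_attention.parameters()
                + self.out_dense.parameters())

    def forward(self, tokens: np.ndarray, meta: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> nn.Tensor:
        xs = [nn.embedding(self.embedding, tokens[:, t]) for t in range(tokens.shape[1])]
        hs = self.enc_bigru.run(xs)
        hs = self.enc_gru.run(hs)
        latent = self.enc_attention.pool(hs)
        if train and self.dropout > 0:
            latent = nn.dropout(latent, self.dropout, rng)
        fused = nn.mul(latent, self.meta_dense(nn.Tensor(meta)))
        batch = tokens.shape[0]
        dec_in = [nn.concat([fused, nn.embedding(self.pos_embedding,
                                                 np.full(batch, t))], axis=1)
                  for t in range(29)]
        dec = self.dec_bigru.run(dec_in)
        alpha = self.dec_attention.weights(dec)
        outs = [self.out_dense(nn.mul(dec[t], nn.column(alpha, t))) for t in range(29)]
        return nn.concat(outs, axis=1)  # (B, 174)


class GRUIntensityPredictor(BaseEstimator):
    """sklearn-style estimator for masked b/y fragment-intensity prediction.

    ``fit(X, y)`` takes a frame with columns modified_sequence,
    precursor_charge, nce and a (n, 174) target matrix (masked entries -1);
    ``predict(X)`` returns non-negative, base-peak-normalized 174-vectors
    with masked entries restored to -1.
    """

    def __init__(self, units: int = 64, dec_units: int = 32, embed_dim: int = 24,
                 dropout: float = 0.1, train_config: TrainConfig | None = None,
                 random_state: int = 0):
        self.units = units
        self.dec_units = dec_units
        self.embed_dim = embed_dim
        self.dropout = dropout
        self.train_config = train_config
        self.random_state = random_state

    # -- training ----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y: np.ndarray,
            validation: tuple[pd.DataFrame, np.ndarray] | None = None
            ) -> "GRUIntensityPredictor":
        cfg = self.train_config or TrainConfig(seed=self.random_state)
        rng = np.random.default_rng(cfg.seed)
        self.net_ = _IntensityNet(self.units, self.dec_units, self.embed_dim,
                                  self.dropout, rng)
        params = self.net_.parameters()
        optimizer = nn.Adam(params)
        tokens, meta, masks = encode_frame(X)
        y = np.asarray(y, dtype=float)
        n = len(X)
        cfg.steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
        if validation is not None:
            val_tokens, val_meta, val_masks = encode_frame(validation[0])
            val_y = np.asarray(validation[1], dtype=float)
        best_loss, best_state, best_epoch = np.inf, None, -1
        self.history_ = []
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for step in range(cfg.steps_per_epoch):
                idx = order[step * cfg.batch_size:(step + 1) * cfg.batch_size]
                if idx.size == 0:
                    continue
                out = self.net_.forward(tokens[idx], meta[idx], train=True, rng=rng)
                loss = nn.masked_spectral_angle_loss(out, np.clip(y[idx], 0, None),
                                                     masks[idx].astype(float))
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"divergent loss at epoch {epoch} step {step}: {loss.data}")
                optimizer.zero_grad()
                loss.backward()
                optimizer.step(clr_schedule(step, epoch, cfg))
                epoch_loss += float(loss.data) * idx.size
            epoch_loss /= n
            if validation is not None:
                monitor = self._evaluate_loss(val_tokens, val_meta, val_masks, val_y)
            else:
                monitor = epoch_loss
            self.history_.append({"epoch": epoch, "train_loss": epoch_loss,
                                  "monitor_loss": monitor})
            if monitor < best_loss - 1e-6:
                best_loss, best_epoch = monitor, epoch
                best_state = [p.data.copy() for p in params]
            elif epoch - best_epoch >= cfg.patience:
                break
        if best_state is not None:
            for p, saved in zip(params, best_state):
                p.data = saved
        self.best_loss_ = best_loss
        self.n_epochs_ = len(self.history_)
        return self

    def _evaluate_loss(self, tokens, meta, masks, y, batch: int = 512) -> float:
        total = 0.0
        for lo in range(0, len(tokens), batch):
            sl = slice(lo, lo + batch)
            out = self.net_.forward(tokens[sl], meta[sl])
            loss = nn.masked_spectral_angle_loss(out, np.clip(y[sl], 0, None),
                                                 masks[sl].astype(float))
            total += float(loss.data) * (min(len(tokens), lo + batch) - lo)
        return total / len(tokens)

    # -- inference ---------------------------------------------------------
    def predict(self, X: pd.DataFrame, batch: int = 512) -> np.ndarray:
        tokens, meta, masks = encode_frame(X)
        raw = np.empty((len(X), FLAT_DIM))
        for lo in range(0, len(X), batch):
            sl = slice(lo, lo + batch)
            raw[sl] = self.net_.forward(tokens[sl], meta[sl]).data
        out = np.clip(raw, 0.0, None)
        peaks = np.where(masks, out, 0.0).max(axis=1)
        scale = np.where(peaks > 0, peaks, 1.0)[:, None]
        out = out / scale
        out[~masks] = -1.0
        return out

    def predict_matrix(self, peptide: Peptide, nce: float) -> FragmentMatrix:
        frame = pd.DataFrame({"modified_sequence": [peptide.modified_sequence],
                              "precursor_charge": [peptide.precursor_charge],
                              "nce": [nce]})
        return FragmentMatrix.from_flat(self.predict(frame)[0], len(peptide),
                                        peptide.precursor_charge)

    def median_holdout_sa(self, X: pd.DataFrame, y: np.ndarray) -> float:
        _, _, masks = encode_frame(X)
        return float(np.median(flat_spectral_angles(self.predict(X), np.asarray(y), masks)))

    # -- persistence -------------------------------------------------------
    def save(self, path: str) -> None:
        cfg = self.train_config or TrainConfig(seed=self.random_state)
        config = {"units": self.units, "dec_units": self.dec_units,
                  "embed_dim": self.embed_dim, "dropout": self.dropout,
                  "random_state": self.random_state, "train_config": asdict(cfg)}
        arrays = {f"param_{i}": p.data for i, p in enumerate(self.net_.parameters())}
        np.savez(path, config=json.dumps(config), **arrays)

    @classmethod
    def load(cls, path: str) -> "GRUIntensityPredictor":
        stash = np.load(path, allow_pickle=False)
        config = json.loads(str(stash["config"]))
        train_cfg = TrainConfig(**config.pop("train_config"))
        model = cls(train_config=train_cfg, **config)
        model.net_ = _IntensityNet(model.units, model.dec_units, model.embed_dim,
                                   model.dropout, np.random.default_rng(0))
        for i, p in enumerate(model.net_.parameters()):
            p.data = stash[f"param_{i}"]
        return model


def calibrate_ce(predictor, frame: pd.DataFrame, observed: np.ndarray,
                 grid=range(20, 41)) -> tuple[float, pd.DataFrame]:
    """Pick the NCE maximising median SA over a confident calibration set.

    ``observed`` is the (n, 174) annotated tensor for the calibration PSMs.
    Ties go to the lower NCE; the median-SA curve is returned for audit.
    """
    grid = list(grid)
    if len(frame) == 0:
        raise ValueError("empty collision-energy calibration set")
    _, _, masks = encode_frame(frame)
    observed = np.asarray(observed, dtype=float)
    medians = []
    for nce in grid:
        probe = frame.copy()
        probe["nce"] = float(nce)
        pred = predictor.predict(probe)
        medians.append(float(np.median(flat_spectral_angles(pred, observed, masks))))
    curve = pd.DataFrame({"nce": grid, "median_sa": medians})
    best = curve.loc[curve["median_sa"].idxmax(), "nce"]  # idxmax: first max, lower NCE
    return float(best), curve
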