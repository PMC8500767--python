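"""LSTM-fused channel-FCN: sequence encoding, residual counting, losses.

Patch sequences (row-major slide order) are encoded per patch by a shared
fully convolutional density network (the channel FCN); a dimension-shuffle
layer pools each predicted map into a fixed-length descriptor sequence that
an LSTM (10 cells by default) consumes to emit a per-patch residual count R.
The integrated tumor mass of patch i is ``T_i = R_i + sum_p F_i(p)``.

Losses::

    L_t    = 1/(2N) sum_i sum_p (F_i(p) - F0_i(p))^2     (density term)
    L_lstm = 1/(2N) sum_i (T_i - T0_i)^2                 (residual term)
    L      = L_t + alpha * L_lstm

with N the sequence (batch) length and alpha a nonnegative weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import nn
from .backbone import BackboneConfig, DeconvNet, _as_input
from .search import lci_to_coords


@dataclass
class LossWeights:
    """Weight of the LSTM residual term in the composite loss."""

    alpha: float = 0.1

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")


def encode_sequence(model, patches):
    """Per-patch density maps from the shared channel FCN (order-preserving).

    ``patches`` is an (N, h, w, 3) stack or list of equally sized images;
    mixed sizes raise.  Returns an (N, h, w) nonnegative array.
    """
    if isinstance(patches, (list, tuple)):
        shapes = {np.asarray(p).shape for p in patches}
        if len(shapes) > 1:
            raise ValueError(f"mixed patch sizes in sequence: {sorted(shapes)}")
        patches = np.stack([np.asarray(p) for p in patches])
    x = _as_input(patches)
    out = model.forward_density(x, train=False)[:, 0]
    return np.maximum(out, 0.0)


def dimension_shuffle(maps, grid=(4, 4)):
    """Pool density maps into LSTM-consumable descriptors (order-preserving).

    Rearranges the (sequence, height, width) stack into a sequence of
    fixed-length vectors: each map is summed over a ``grid`` of near-equal
    spatial cells, so each descriptor sums to its map's integral.
    """
    maps = np.asarray(maps, dtype=np.float64)
    n, h, w = maps.shape
    gr, gc = grid
    r_edges = np.linspace(0, h, gr + 1).astype(int)[:-1]
    c_edges = np.linspace(0, w, gc + 1).astype(int)[:-1]
    pooled = np.add.reduceat(np.add.reduceat(maps, r_edges, axis=1), c_edges, axis=2)
    return pooled.reshape(n, gr * gc)


class _ShuffleLayer(nn.Layer):
    """dimension_shuffle as a differentiable layer: (N,1,h,w) -> (N, gr*gc).

    ``out_scale`` rescales the pooled sums (grid-cell sums of a mask-scale
    map grow with the cell area, which would saturate the LSTM gates).
    """

    def __init__(self, grid=(4, 4), out_scale=1.0):
        self.grid = grid
        self.out_scale = out_scale

    def forward(self, x, train=False):
        n, _, h, w = x.shape
        if train:
            self._shape = x.shape
        pooled = dimension_shuffle(x[:, 0], self.grid)
        return (pooled * self.out_scale).astype(nn.DTYPE)

    def backward(self, dy):
        n, _, h, w = self._shape
        gr, gc = self.grid
        r_edges = np.linspace(0, h, gr + 1).astype(int)
        c_edges = np.linspace(0, w, gc + 1).astype(int)
        dx = np.zeros((n, 1, h, w), nn.DTYPE)
        dcell = (dy * self.out_scale).reshape(n, gr, gc)
        for i in range(gr):
            for j in range(gc):
                dx[:, 0, r_edges[i]:r_edges[i + 1], c_edges[j]:c_edges[j + 1]] = \
                    dcell[:, i, j][:, None, None]
        return dx


def lstm_residual(descriptors, lstm, readout):
    """Per-patch residual counts R_i from a descriptor sequence."""
    d = np.asarray(descriptors, dtype=nn.DTYPE)
    if d.ndim != 2 or len(d) == 0:
        raise ValueError("descriptors must be a nonempty (N, d) sequence")
    hs = lstm.forward(d[None], train=False)
    return readout.forward(hs[0], train=False)[:, 0].astype(np.float64)


def integrated_count(density_map, residual):
    """T_i = R_i + sum_p F_i(p)."""
    return float(residual) + float(np.sum(density_map))


def loss_tissue(pred, gt):
    """L_t = 1/(2N) sum_i sum_p (F_i(p) - F0_i(p))^2."""
    pred = [np.asarray(p, dtype=np.float64) for p in pred]
    gt = [np.asarray(g, dtype=np.float64) for g in gt]
    if len(pred) != len(gt):
        raise ValueError("prediction/truth length mismatch")
    for p, g in zip(pred, gt):
        if p.shape != g.shape:
            raise ValueError(f"map shape mismatch {p.shape} vs {g.shape}")
    n = len(pred)
    return sum(float(np.sum((p - g) ** 2)) for p, g in zip(pred, gt)) / (2 * n)


def loss_lstm(T, T0):
    """L_lstm = 1/(2N) sum_i (T_i - T0_i)^2."""
    T = np.asarray(T, dtype=np.float64)
    T0 = np.asarray(T0, dtype=np.float64)
    if T.shape != T0.shape:
        raise ValueError("count list length mismatch")
    n = len(T)
    return float(np.sum((T - T0) ** 2)) / (2 * n)


def total_loss(l_tissue, l_lstm, weights=None):
    """L = L_t + alpha * L_lstm."""
    weights = weights or LossWeights()
    return float(l_tissue) + weights.alpha * float(l_lstm)


def stitch_density(maps, lcis, level_dims, patch_size=None):
    """Assemble per-patch density maps into a whole-level map by LCI position.

    Each map is written at its location code's decoded origin; unfilled
    pixels stay zero; overlapping LCIs raise.
    """
    maps = [np.asarray(m, dtype=np.float64) for m in maps]
    if len(maps) != len(lcis):
        raise ValueError("maps and LCIs must match one-to-one")
    out = np.zeros(level_dims, dtype=np.float64)
    occupied = np.zeros(level_dims, dtype=bool)
    levels = set()
    for m, lci in zip(maps, lcis):
        ps = patch_size if patch_size is not None else m.shape[0]
        level, (r, c) = lci_to_coords(lci, ps)
        levels.add(level)
        if len(levels) > 1:
            raise ValueError("LCIs decode to different levels")
        h, w = m.shape
        if r < 0 or c < 0 or r + h > level_dims[0] or c + w > level_dims[1]:
            raise ValueError(f"patch at {(r, c)} exceeds level dims {level_dims}")
        if occupied[r:r + h, c:c + w].any():
            raise ValueError(f"overlapping LCIs at {(r, c)}")
        out[r:r + h, c:c + w] = m
        occupied[r:r + h, c:c + w] = True
    return out


class SequenceDensityCounter(BaseEstimator):
    """Jointly trained channel-FCN + LSTM residual counter.

    ``fit`` takes sequences of ``(patches, gt_maps, gt_counts)`` (arrays of
    shape (N, h, w, 3), (N, h, w), (N,)); the composite loss L = L_t +
    alpha * L_lstm is minimized with Adam, backpropagating through the LSTM
    over the full sequence (truncation window = sequence length at desk
    scale).  ``predict_counts`` returns the integrated per-patch masses
    T_i = R_i + sum F_i.
    """

    def __init__(self, base_filters=8, n_blocks=3, hidden_size=10, alpha=0.1,
                 grid=(4, 4), epochs=40, lr_initial=1e-3, lr_final=1e-5,
                 batch_sequences=4, random_state=0):
        self.base_filters = base_filters
        self.n_blocks = n_blocks
        self.hidden_size = hidden_size
        self.alpha = alpha
        self.grid = grid
        self.epochs = epochs
        self.lr_initial = lr_initial
        self.lr_final = lr_final
        self.batch_sequences = batch_sequences
        self.random_state = random_state

    def _build(self, patch_shape):
        config = BackboneConfig(base_filters=self.base_filters,
                                n_down_blocks=self.n_blocks,
                                n_up_blocks=self.n_blocks)
        self.cfcn_ = DeconvNet(config, seed=self.random_state)
        rng = np.random.default_rng(self.random_state + 7)
        # normalize grid-cell sums by cell area so LSTM inputs stay O(1)
        h, w = patch_shape
        self.descriptor_scale_ = (self.grid[0] * self.grid[1]) / float(h * w)
        self.shuffle_ = _ShuffleLayer(self.grid, out_scale=self.descriptor_scale_)
        self.lstm_ = nn.LSTM(self.grid[0] * self.grid[1], self.hidden_size, rng)
        self.readout_ = nn.Dense(self.hidden_size, 1, rng)

    def _forward_train(self, patches):
        x = _as_input(patches)
        F_raw = self.cfcn_.forward_density(x, train=True)  # (N,1,h,w)
        desc = self.shuffle_.forward(F_raw, train=True)    # (N,16)
        hs = self.lstm_.forward(desc[None], train=True)    # (1,N,H)
        R = self.readout_.forward(hs[0], train=True)[:, 0]  # (N,)
        return F_raw, desc, R

    def _step(self, sequences_batch, opt, lr):
        """One Adam step on a batch of sequences; returns (L_t, L_lstm, L)."""
        opt.zero_grad()
        lt_sum = ll_sum = 0.0
        scale = 1.0 / len(sequences_batch)
        for patches, gt_maps, gt_counts in sequences_batch:
            n = len(patches)
            F_raw, desc, R = self._forward_train(patches)
            F = F_raw[:, 0].astype(np.float64)
            F0 = np.asarray(gt_maps, dtype=np.float64)
            T = R.astype(np.float64) + F.sum(axis=(1, 2))
            T0 = np.asarray(gt_counts, dtype=np.float64)
            lt = float(np.sum((F - F0) ** 2)) / (2 * n)
            ll = float(np.sum((T - T0) ** 2)) / (2 * n)
            lt_sum += lt
            ll_sum += ll
            dT = scale * self.alpha * (T - T0) / n               # (N,)
            dR = dT.astype(nn.DTYPE)
            dh = self.readout_.backward(dR[:, None])             # (N,H)
            ddesc = self.lstm_.backward(dh[None])[0]             # (N,16)
            dF = self.shuffle_.backward(ddesc)                   # (N,1,h,w)
            dF += (scale * (F - F0) / n
                   + dT[:, None, None])[:, None].astype(nn.DTYPE)
            self.cfcn_.backward_density(dF)
        opt.step(lr=lr)
        m = len(sequences_batch)
        return lt_sum / m, ll_sum / m, lt_sum / m + self.alpha * ll_sum / m

    def fit(self, sequences):
        if len(sequences) == 0:
            raise ValueError("empty dataset")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")
        self._build(np.asarray(sequences[0][0]).shape[1:3])
        params = (self.cfcn_.parameters("density") + self.lstm_.params()
                  + self.readout_.params())
        opt = nn.Adam(params, lr=self.lr_initial)
        rng = np.random.default_rng(self.random_state)
        log = []
        for epoch in range(self.epochs):
            lr = nn.lr_schedule(epoch, self.epochs, self.lr_initial, self.lr_final)
            order = rng.permutation(len(sequences))
            lt_e = ll_e = l_e = 0.0
            n_batches = 0
            for start in range(0, len(sequences), self.batch_sequences):
                batch = [sequences[i] for i in order[start:start + self.batch_sequences]]
                lt, ll, ltot = self._step(batch, opt, lr)
                if not np.isfinite(ltot):
                    raise FloatingPointError(f"NaN loss at epoch {epoch}")
                lt_e += lt
                ll_e += ll
                l_e += ltot
                n_batches += 1
            log.append({"epoch": epoch, "L_t": lt_e / n_batches,
                        "L_lstm": ll_e / n_batches, "L": l_e / n_batches})
        self.loss_log_ = pd.DataFrame(log)
        return self

    def predict_counts(self, patches):
        """Integrated per-patch tumor masses T_i for one sequence."""
        F = encode_sequence(self.cfcn_, patches)
        desc = dimension_shuffle(F, self.grid) * self.descriptor_scale_
        R = lstm_residual(desc, self.lstm_, self.readout_)
        return R + F.sum(axis=(1, 2))

    def log_to_csv(self, path):
        """Write the per-epoch loss log as ``epoch,L_t,L_lstm,L``."""
        self.loss_log_.to_csv(path, index=False)
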