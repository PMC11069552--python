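"""Deep auto-encoder imputation for mixed-type encoded tables.

A single sigmoid encoder layer maps an encoded row ``a`` to a hidden code
``b = sigmoid(W a + beta)``; the decoder maps ``b`` back through an affine
layer whose output is left linear on coordinates derived from continuous
columns (squared-error loss, no squashing) and passed through a sigmoid on
coordinates derived from binary/one-hot columns (cross-entropy loss).  The
loss is restricted to observed cells; missing inputs start at the observed
column means and are periodically overwritten by the current reconstruction
(iterative re-feeding), so the network gradually commits to its own
imputations.

The public surface follows the fitted-model idiom: build a
:class:`DAEMImputer` from an :class:`~dacl.schema.EncodedMatrix`, call
``fit()``, and use the returned :class:`DAEMResults` to reconstruct or
impute tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, sigmoid
from .schema import DataTable, EncodedMatrix, decode_matrix, encode_table

__all__ = ["DAEMConfig", "DAEMParams", "DAEMImputer", "DAEMResults",
           "daem_encode", "daem_decode", "masked_reconstruction_loss",
           "train_daem", "impute", "mean_impute_baseline"]


@dataclass(frozen=True)
class DAEMConfig:
    hidden_dim: int | None = None      # default: narrow bottleneck, see fit()
    epochs: int = 300
    learning_rate: float = 1e-3
    batch_size: int = 64
    refeed_rounds: int = 3
    weight_decay: float = 3e-3         # L2 shrinkage; damps identity shortcuts
    seed: int = 0

    def __post_init__(self):
        if self.hidden_dim is not None and self.hidden_dim < 1:
            raise ValueError("hidden_dim must be >= 1")
        if self.refeed_rounds < 1:
            raise ValueError("refeed_rounds must be >= 1")


@dataclass
class DAEMParams:
    """Encoder/decoder weights: b = sigma(W a + beta), z = W' b + beta'."""
    W: np.ndarray        # d_in x d_hidden
    beta: np.ndarray     # d_hidden
    W_dec: np.ndarray    # d_hidden x d_in
    beta_dec: np.ndarray # d_in

    def __post_init__(self):
        if self.W.shape[1] != self.beta.shape[0] or self.W_dec.shape != self.W.T.shape \
                or self.beta_dec.shape[0] != self.W.shape[0]:
            raise ValueError("inconsistent parameter shapes")
        for p in (self.W, self.beta, self.W_dec, self.beta_dec):
            if not np.all(np.isfinite(p)):
                raise ValueError("non-finite parameters")

    @property
    def d_in(self) -> int:
        return self.W.shape[0]


def daem_encode(a: np.ndarray, params: DAEMParams) -> np.ndarray:
    """Hidden code b = sigmoid(W a + beta); accepts a row or a batch."""
    single = np.ndim(a) == 1
    a = np.atleast_2d(a)
    if a.shape[1] != params.d_in:
        raise ValueError(f"input width {a.shape[1]} != {params.d_in}")
    b = sigmoid(a @ params.W + params.beta)
    return b[0] if single else b


def _encode_batch(a: np.ndarray, params: DAEMParams) -> np.ndarray:
    return sigmoid(a @ params.W + params.beta)


def daem_decode(b: np.ndarray, params: DAEMParams,
                continuous_idx: np.ndarray, discrete_idx: np.ndarray) -> np.ndarray:
    """Reconstruction: linear on continuous coordinates, sigmoid on discrete."""
    single = np.ndim(b) == 1
    b = np.atleast_2d(b)
    if b.shape[1] != params.W_dec.shape[0]:
        raise ValueError("hidden width mismatch")
    z = b @ params.W_dec + params.beta_dec
    c = z.copy()
    if discrete_idx.size:
        c[:, discrete_idx] = sigmoid(z[:, discrete_idx])
    return c[0] if single else c


def masked_reconstruction_loss(batch: np.ndarray, mask: np.ndarray, recon: np.ndarray,
                               continuous_idx: np.ndarray, discrete_idx: np.ndarray,
                               eps: float = 1e-7) -> float:
    """Mean over observed cells: squared error (continuous) + cross-entropy (discrete)."""
    if batch.shape != recon.shape or batch.shape != mask.shape:
        raise ValueError("shape mismatch")
    observed = ~mask
    if not observed.any():
        raise ValueError("batch has no observed cells")
    total, count = 0.0, 0
    if continuous_idx.size:
        obs = observed[:, continuous_idx]
        diff = (batch[:, continuous_idx] - recon[:, continuous_idx]) ** 2
        total += float(diff[obs].sum())
        count += int(obs.sum())
    if discrete_idx.size:
        obs = observed[:, discrete_idx]
        p = np.clip(recon[:, discrete_idx], eps, 1.0 - eps)
        t = batch[:, discrete_idx]
        ce = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))
        total += float(ce[obs].sum())
        count += int(obs.sum())
    return total / count


@dataclass
class DAEMResults:
    """Fitted imputer: trained parameters, the training trace, and the
    encoding map of the data the model was fitted on."""
    params: DAEMParams
    config: DAEMConfig
    loss_history: list[float]
    encoding_map: dict
    continuous_idx: np.ndarray
    discrete_idx: np.ndarray
    column_means: np.ndarray

    def reconstruct(self, matrix: np.ndarray) -> np.ndarray:
        b = _encode_batch(matrix, self.params)
        return daem_decode(b, self.params, self.continuous_idx, self.discrete_idx)

    def impute_matrix(self, enc: EncodedMatrix, refinements: int = 3) -> np.ndarray:
        """Fill missing cells of an encoded matrix; observed cells untouched."""
        if enc.matrix.shape[1] != self.params.d_in:
            raise ValueError("encoded width does not match fitted model")
        filled = enc.matrix.copy()
        filled[enc.mask] = np.broadcast_to(self.column_means, filled.shape)[enc.mask]
        for _ in range(refinements):
            recon = np.atleast_2d(self.reconstruct(filled))
            filled[enc.mask] = recon[enc.mask]
        return filled

    def impute_table(self, table: DataTable) -> DataTable:
        """Impute a schema-typed table.  Observed cells are preserved exactly;
        missing cells are reconstructed and decoded back to schema types."""
        return impute(table, self)

    def summary(self) -> str:
        lines = [
            "DAEM imputation results",
            "=" * 38,
            f"input width:        {self.params.d_in}",
            f"hidden width:       {self.params.W.shape[1]}",
            f"epochs:             {self.config.epochs}",
            f"refeed rounds:      {self.config.refeed_rounds}",
            f"final masked loss:  {self.loss_history[-1]:.6f}",
        ]
        return "\n".join(lines)


class DAEMImputer:
    """Auto-encoder imputation model over an :class:`EncodedMatrix`."""

    def __init__(self, enc: EncodedMatrix, config: DAEMConfig | None = None):
        if (enc.mask.all(axis=0)).any():
            raise ValueError("every column needs at least one observed cell")
        self.enc = enc
        self.config = config or DAEMConfig()

    @classmethod
    def from_table(cls, table: DataTable, config: DAEMConfig | None = None) -> "DAEMImputer":
        return cls(encode_table(table), config)

    def fit(self) -> DAEMResults:
        cfg = self.config
        X, M = self.enc.matrix, self.enc.mask
        n, d = X.shape
        # narrow bottleneck: wide codes let the network copy inputs through,
        # which reconstructs observed cells but tells missing cells nothing
        d_hidden = cfg.hidden_dim or max(2, int(np.ceil(d / 4)))
        rng = np.random.default_rng(cfg.seed)

        cont, disc = self.enc.continuous_idx, self.enc.discrete_idx
        col_means = np.array([X[~M[:, j], j].mean() if (~M[:, j]).any() else 0.0
                              for j in range(d)])
        filled = X.copy()
        filled[M] = np.broadcast_to(col_means, X.shape)[M]

        limit = np.sqrt(6.0 / (d + d_hidden))
        params = DAEMParams(
            W=rng.uniform(-limit, limit, size=(d, d_hidden)),
            beta=np.zeros(d_hidden),
            W_dec=rng.uniform(-limit, limit, size=(d_hidden, d)),
            beta_dec=np.zeros(d),
        )
        opt = Adam([params.W, params.beta, params.W_dec, params.beta_dec],
                   lr=cfg.learning_rate)

        history: list[float] = []
        epochs_per_round = max(1, cfg.epochs // cfg.refeed_rounds)
        epoch = 0
        while epoch < cfg.epochs:
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                a, m = filled[idx], M[idx]
                obs = ~m
                n_obs = obs.sum()
                if n_obs == 0:
                    continue
                b = sigmoid(a @ params.W + params.beta)
                z = b @ params.W_dec + params.beta_dec
                c = z.copy()
                if disc.size:
                    c[:, disc] = sigmoid(z[:, disc])

                # d(loss)/d(z): for squared error on linear coords 2(c-a)/n_obs,
                # for cross-entropy through sigmoid (c-a)/n_obs — both (c - a)
                # up to the factor 2, folded per coordinate kind.
                dz = np.zeros_like(z)
                if cont.size:
                    dz[:, cont] = 2.0 * (c[:, cont] - a[:, cont])
                if disc.size:
                    dz[:, disc] = c[:, disc] - a[:, disc]
                dz[m] = 0.0
                dz /= n_obs

                dW_dec = b.T @ dz + cfg.weight_decay * params.W_dec
                dbeta_dec = dz.sum(axis=0)
                db = dz @ params.W_dec.T
                dpre = db * b * (1.0 - b)
                dW = a.T @ dpre + cfg.weight_decay * params.W
                dbeta = dpre.sum(axis=0)

                loss = masked_reconstruction_loss(a, m, c, cont, disc)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite reconstruction loss at epoch {epoch}")
                opt.step([dW, dbeta, dW_dec, dbeta_dec])
                epoch_loss += loss
                n_batches += 1
            history.append(epoch_loss / max(n_batches, 1))
            epoch += 1
            if epoch % epochs_per_round == 0 and M.any():
                recon = daem_decode(_encode_batch(filled, params), params, cont, disc)
                filled[M] = np.atleast_2d(recon)[M]

        return DAEMResults(params=params, config=cfg, loss_history=history,
                           encoding_map=self.enc.encoding_map,
                           continuous_idx=cont, discrete_idx=disc,
                           column_means=col_means)


def train_daem(enc: EncodedMatrix, config: DAEMConfig | None = None) -> DAEMResults:
    """Functional wrapper: fit a DAEM on an encoded matrix."""
    return DAEMImputer(enc, config).fit()


def impute(table: DataTable, results: DAEMResults) -> DataTable:
    """Replace the missing cells of ``table`` with DAEM reconstructions.

    Observed cells are preserved bit-for-bit; the output mask is all-false.
    """
    if not table.missing_mask.any():
        return table.copy()
    enc = encode_table(table)
    if enc.matrix.shape[1] != results.params.d_in:
        raise ValueError("table encoding width does not match fitted model")
    filled = results.impute_matrix(enc)
    enc_filled = EncodedMatrix(filled, np.zeros_like(enc.mask), enc.encoding_map,
                               enc.label_vector)
    id_vals = (table.values[table.schema.id_column].to_numpy()
               if table.schema.id_column else None)
    decoded = decode_matrix(enc_filled, table.schema, id_values=id_vals)
    # restore observed cells exactly (decoding can lose precision via scaling)
    out_vals = decoded.values.copy()
    for j, col in enumerate(table.schema.columns):
        obs = ~table.missing_mask[:, j]
        src = table.values[col.name].to_numpy()
        dst = out_vals[col.name].to_numpy(copy=True)
        if col.kind == "numeric":
            dst = dst.astype(float)
        dst[obs] = src[obs]
        out_vals[col.name] = dst
    return DataTable(table.schema, out_vals,
                     np.zeros_like(table.missing_mask))


def imputation_rmse(truth: DataTable, imputed: DataTable,
                    mask: np.ndarray) -> float:
    """RMSE over the masked cells on the encoded scale.

    Numeric cells contribute (imputed - truth) / (observed column range);
    binary and categorical cells contribute 0/1 level mismatch.  This makes
    mixed-type errors commensurate with the [0, 1] encoding geometry.
    """
    errs = []
    for j, col in enumerate(truth.schema.columns):
        m = mask[:, j]
        if not m.any():
            continue
        tv = truth.values[col.name].to_numpy()
        iv = imputed.values[col.name].to_numpy()
        if col.kind == "numeric":
            t = tv.astype(float)
            span = float(t.max() - t.min()) or 1.0
            errs.extend(((iv[m].astype(float) - t[m]) / span) ** 2)
        else:
            errs.extend((tv[m].astype(str) != iv[m].astype(str)).astype(float))
    if not errs:
        raise ValueError("mask selects no cells")
    return float(np.sqrt(np.mean(errs)))


def mean_impute_baseline(table: DataTable) -> DataTable:
    """Column-mean / column-mode imputation, the baseline DAEM must beat."""
    out_vals = table.values.copy()
    for j, col in enumerate(table.schema.columns):
        miss = table.missing_mask[:, j]
        if not miss.any():
            continue
        vals = out_vals[col.name].to_numpy(copy=True)
        if col.kind == "numeric":
            vals = vals.astype(float)
            vals[miss] = np.nanmean(vals[~miss].astype(float))
        else:
            observed = vals[~miss]
            levels, counts = np.unique(observed.astype(str), return_counts=True)
            vals[miss] = levels[counts.argmax()]
        out_vals[col.name] = vals
    return DataTable(table.schema, out_vals, np.zeros_like(table.missing_mask))
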