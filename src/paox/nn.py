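"""Minimal neural-network engine for the oximetry regressors.

Implements exactly the two architectures the package needs — a
wavelength-masked LSTM regressor and a fixed-wavelength feedforward
regressor — with analytic backpropagation, the Adam optimizer, mean
absolute error loss, and a reduce-on-plateau learning-rate schedule.
Everything runs in float32 on the CPU; training is deterministic given the
seed (single-threaded BLAS).

Masking semantics of the LSTM (the wavelength-flexibility mechanism): at a
masked step the recurrent state passes through unchanged and the emitted
hidden vector repeats the previously emitted one; steps before the first
present wavelength emit zeros.  Stored amplitude values at masked slots
therefore never influence the output.

Implementation note: large per-batch intermediates (the per-step gate and
state tensors, dense-layer activations and weight gradients) are reused
across batches through a per-network buffer pool — repeated fresh mmap-size
allocations otherwise dominate the runtime of CPU training.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _sigmoid(x):
    # exp overflow saturates to inf -> sigmoid 0, which is the correct limit
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-x))


def _sigmoid_inplace(x):
    with np.errstate(over="ignore"):
        np.negative(x, out=x)
        np.exp(x, out=x)
        x += 1.0
        np.reciprocal(x, out=x)
    return x


def _glorot(rng, shape):
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _orthogonal_recurrent(rng, hidden, n_gates=4):
    blocks = []
    for _ in range(n_gates):
        a = rng.standard_normal((hidden, hidden))
        q, r = np.linalg.qr(a)
        q *= np.sign(np.diag(r))
        blocks.append(q.astype(DTYPE))
    return np.concatenate(blocks, axis=1)  # (H, 4H)


def _dense_stack_init(rng, sizes):
    params = {}
    for li in range(len(sizes) - 1):
        params[f"W{li+1}"] = _glorot(rng, (sizes[li], sizes[li + 1]))
        params[f"b{li+1}"] = np.zeros(sizes[li + 1], dtype=DTYPE)
    return params


class _Pool:
    """Shape-checked scratch-buffer reuse across batches."""

    def __init__(self):
        self._bufs = {}

    def get(self, key, shape):
        buf = self._bufs.get(key)
        if buf is None or buf.shape != shape:
            buf = np.empty(shape, dtype=DTYPE)
            self._bufs[key] = buf
        return buf


def _head_forward(params, n_layers, x, alpha, pool, tag=""):
    """Dense stack with leaky-ReLU between layers and sigmoid output."""
    acts = [x]
    zs = []
    a = x
    B = x.shape[0]
    for li in range(1, n_layers + 1):
        W = params[f"W{li}"]
        z = pool.get(f"{tag}z{li}", (B, W.shape[1]))
        np.matmul(a, W, out=z)
        z += params[f"b{li}"]
        zs.append(z)
        if li == n_layers:
            a = _sigmoid(z)
        else:
            # leaky ReLU: max(z, alpha*z) since 0 < alpha < 1
            a = pool.get(f"{tag}a{li}", z.shape)
            np.multiply(z, alpha, out=a)
            np.maximum(z, a, out=a)
        acts.append(a)
    return acts[-1], (acts, zs)


def _head_backward(params, n_layers, dp, cache, alpha, pool, tag=""):
    acts, zs = cache
    grads = {}
    p = acts[-1]
    delta = dp * p * (1.0 - p)  # through the output sigmoid
    for li in range(n_layers, 0, -1):
        W = params[f"W{li}"]
        gW = pool.get(f"{tag}gW{li}", W.shape)
        np.matmul(acts[li - 1].T, delta, out=gW)
        grads[f"W{li}"] = gW
        grads[f"b{li}"] = delta.sum(axis=0)
        da = pool.get(f"{tag}da{li}", (delta.shape[0], W.shape[0]))
        np.matmul(delta, W.T, out=da)
        if li > 1:
            z = zs[li - 2]
            slope = pool.get(f"{tag}sl{li}", z.shape)
            np.multiply((z >= 0), 1.0 - alpha, out=slope, casting="unsafe")
            slope += alpha  # 1 where z >= 0, alpha elsewhere
            np.multiply(da, slope, out=da)
            delta = da
    return grads, da  # da from li == 1 is the input gradient


class MaskedLstmNet:
    """41-step masked LSTM + flattened encoding + 3-layer dense head."""

    def __init__(self, n_steps=41, hidden=100, fc_hidden=1000, leaky_alpha=0.01, seed=0):
        self.n_steps = int(n_steps)
        self.hidden = int(hidden)
        self.fc_hidden = int(fc_hidden)
        self.alpha = float(leaky_alpha)
        self.fc_input = self.n_steps * self.hidden
        rng = np.random.default_rng(seed)
        H = self.hidden
        self.params = {
            "Wx": _glorot(rng, (1, 4 * H)),
            "Wh": _orthogonal_recurrent(rng, H),
            "bh": np.zeros(4 * H, dtype=DTYPE),
        }
        self.params["bh"][H:2 * H] = 1.0  # forget-gate bias
        self.params.update(_dense_stack_init(rng, [self.fc_input, self.fc_hidden, self.fc_hidden, 1]))
        self._pool = _Pool()

    # -- forward -----------------------------------------------------------
    def forward(self, X, M, need_cache=False):
        """X: (B, T) float32 amplitudes; M: (B, T) bool presence mask."""
        B, T = X.shape
        H = self.hidden
        pool = self._pool
        Wx, Wh, bh = self.params["Wx"], self.params["Wh"], self.params["bh"]
        # input contribution for all steps in one rank-1 gemm
        xw = pool.get("xw", (B, T, 4 * H))
        np.matmul(np.ascontiguousarray(X, dtype=DTYPE).reshape(-1, 1), Wx,
                  out=xw.reshape(B * T, 4 * H))
        xw += bh
        # float masks: blending with multiplies is much faster than np.where
        Mf = M.astype(DTYPE)
        Mi = 1.0 - Mf
        h = np.zeros((B, H), dtype=DTYPE)
        c = np.zeros((B, H), dtype=DTYPE)
        Hs = pool.get("Hs", (T, B, H))
        Cs = pool.get("Cs", (T, B, H))
        gates = pool.get("gates", (T, B, 4 * H)) if need_cache else None
        zbuf = pool.get("z", (B, 4 * H))
        recur = pool.get("recur", (B, 4 * H))
        for t in range(T):
            z = gates[t] if need_cache else zbuf
            np.matmul(h, Wh, out=recur)
            np.add(xw[:, t], recur, out=z)
            g = np.tanh(z[:, 2 * H:3 * H])
            act = _sigmoid_inplace(z)  # i, f, o slices; g slice overwritten below
            act[:, 2 * H:3 * H] = g
            i = act[:, :H]
            f = act[:, H:2 * H]
            o = act[:, 3 * H:]
            mf = Mf[:, t:t + 1]
            mi = Mi[:, t:t + 1]
            c = (f * c + i * g) * mf + c * mi
            h = (o * np.tanh(c)) * mf + h * mi
            Hs[t] = h
            Cs[t] = c
        enc = pool.get("enc", (B, T * H))
        np.copyto(enc.reshape(B, T, H).transpose(1, 0, 2), Hs)
        p, head_cache = _head_forward(self.params, 3, enc, self.alpha, pool)
        cache = (X, M, Mf, Mi, Hs, Cs, gates, head_cache) if need_cache else None
        return p, cache

    # -- backward ----------------------------------------------------------
    def backward(self, dp, cache):
        X, M, Mf, Mi, Hs, Cs, gates, head_cache = cache
        B, T = X.shape
        H = self.hidden
        pool = self._pool
        Wh = self.params["Wh"]
        grads, d_enc = _head_backward(self.params, 3, dp, head_cache, self.alpha, pool)
        dH = d_enc.reshape(B, T, H)

        dWx = np.zeros(4 * H, dtype=DTYPE)
        dWh = np.zeros((H, 4 * H), dtype=DTYPE)
        dbh = np.zeros(4 * H, dtype=DTYPE)
        dh_next = np.zeros((B, H), dtype=DTYPE)
        dc_next = np.zeros((B, H), dtype=DTYPE)
        zeros = np.zeros((B, H), dtype=DTYPE)
        dz = pool.get("dz", (B, 4 * H))
        dwh_t = pool.get("dwh_t", (H, 4 * H))
        dh_rec = pool.get("dh_rec", (B, H))
        for t in range(T - 1, -1, -1):
            mf = Mf[:, t:t + 1]
            mi = Mi[:, t:t + 1]
            dh_total = dH[:, t] + dh_next
            i = gates[t, :, :H]
            f = gates[t, :, H:2 * H]
            g = gates[t, :, 2 * H:3 * H]
            o = gates[t, :, 3 * H:]
            c_prev = Cs[t - 1] if t > 0 else zeros
            h_prev = Hs[t - 1] if t > 0 else zeros
            tanh_c = np.tanh(Cs[t])
            dc = dc_next + dh_total * o * (1.0 - tanh_c * tanh_c)
            np.multiply(dc * g, i * (1.0 - i), out=dz[:, :H])
            np.multiply(dc * c_prev, f * (1.0 - f), out=dz[:, H:2 * H])
            np.multiply(dc * i, 1.0 - g * g, out=dz[:, 2 * H:3 * H])
            np.multiply(dh_total * tanh_c, o * (1.0 - o), out=dz[:, 3 * H:])
            dz *= mf  # masked steps contribute nothing
            dWx += X[:, t] @ dz
            np.matmul(h_prev.T, dz, out=dwh_t)
            dWh += dwh_t
            dbh += dz.sum(axis=0)
            np.matmul(dz, Wh.T, out=dh_rec)
            dh_next = dh_rec + dh_total * mi
            dc_next = dc * f * mf + dc_next * mi
        grads["Wx"] = dWx[None, :]
        grads["Wh"] = dWh
        grads["bh"] = dbh
        return grads


class FeedforwardNet:
    """Fixed-wavelength dense regressor (the wavelength-inflexible baseline).

    Consumes the full 41-channel spectrum directly; rejects masked inputs.
    """

    def __init__(self, n_inputs=41, hidden=(1000, 1000), leaky_alpha=0.01, seed=0):
        self.n_inputs = int(n_inputs)
        self.hidden = tuple(int(h) for h in hidden)
        self.alpha = float(leaky_alpha)
        self.n_layers = len(self.hidden) + 1
        rng = np.random.default_rng(seed)
        self.params = _dense_stack_init(rng, [self.n_inputs, *self.hidden, 1])
        self._pool = _Pool()

    def forward(self, X, M, need_cache=False):
        if not np.all(M):
            raise ValueError("feedforward baseline requires all wavelengths present")
        X = np.ascontiguousarray(X, dtype=DTYPE)
        p, head_cache = _head_forward(self.params, self.n_layers, X, self.alpha, self._pool)
        return p, (head_cache if need_cache else None)

    def backward(self, dp, cache):
        grads, _ = _head_backward(self.params, self.n_layers, dp, cache, self.alpha, self._pool)
        return grads


# --- optimizer and training loop -------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self._scratch = {k: np.empty_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            m, v, tmp = self.m[k], self.v[k], self._scratch[k]
            np.multiply(g, 1.0 - self.beta1, out=tmp)
            m *= self.beta1
            m += tmp
            np.multiply(g, g, out=tmp)
            tmp *= 1.0 - self.beta2
            v *= self.beta2
            v += tmp
            np.divide(v, b2t, out=tmp)
            np.sqrt(tmp, out=tmp)
            tmp += self.eps
            np.divide(m, tmp, out=tmp)
            tmp *= self.lr / b1t
            params[k] -= tmp


class PlateauScheduler:
    """Halve the learning rate when validation loss stalls for ``patience`` epochs."""

    def __init__(self, optimizer, factor=0.5, patience=5, min_lr=1e-6):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.wait = 0

    def step(self, val_loss):
        if val_loss < self.best:
            self.best = val_loss
            self.wait = 0
        else:
            self.wait += 1
            if self.wait >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.wait = 0
        return self.opt.lr


def fit_network(net, X, M, y, *, epochs=30, batch_size=1024, initial_lr=1e-3,
                lr_factor=0.5, lr_patience=5, min_lr=1e-6, val_fraction=0.2,
                seed=0, verbose=False):
    """Train ``net`` with MAE loss and Adam; returns the per-epoch history.

    X (n, T) float amplitudes (z-scored), M (n, T) bool, y (n,) in [0, 1].
    """
    n = X.shape[0]
    X = np.ascontiguousarray(X, dtype=DTYPE)
    M = np.ascontiguousarray(M, dtype=bool)
    y = np.asarray(y, dtype=DTYPE).reshape(-1, 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if val_fraction > 0 else 0
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xt, Mt, yt = X[train_idx], M[train_idx], y[train_idx]
    Xv, Mv, yv = X[val_idx], M[val_idx], y[val_idx]

    opt = Adam(net.params, lr=initial_lr)
    sched = PlateauScheduler(opt, factor=lr_factor, patience=lr_patience, min_lr=min_lr)
    history = []
    n_train = Xt.shape[0]
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n_train)
        train_loss = 0.0
        for start in range(0, n_train, batch_size):
            b = order[start:start + batch_size]
            p, cache = net.forward(Xt[b], Mt[b], need_cache=True)
            resid = p - yt[b]
            train_loss += float(np.abs(resid).sum())
            dp = (np.sign(resid) / len(b)).astype(DTYPE)
            grads = net.backward(dp, cache)
            opt.step(net.params, grads)
        train_loss /= n_train
        val_loss = evaluate_mae(net, Xv, Mv, yv) if n_val else train_loss
        lr_now = sched.step(val_loss)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": lr_now})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.4f}  val {val_loss:.4f}  lr {lr_now:.2e}")
    return history


def evaluate_mae(net, X, M, y, batch_size=1024):
    y = np.asarray(y, dtype=DTYPE).reshape(-1, 1)
    total = 0.0
    for start in range(0, X.shape[0], batch_size):
        p, _ = net.forward(X[start:start + batch_size], M[start:start + batch_size])
        total += float(np.abs(p - y[start:start + batch_size]).sum())
    return total / X.shape[0]


def predict_network(net, X, M, batch_size=1024):
    X = np.ascontiguousarray(X, dtype=DTYPE)
    M = np.ascontiguousarray(M, dtype=bool)
    out = np.empty(X.shape[0], dtype=np.float64)
    for start in range(0, X.shape[0], batch_size):
        p, _ = net.forward(X[start:start + batch_size], M[start:start + batch_size])
        out[start:start + batch_size] = p[:, 0]
    return out
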