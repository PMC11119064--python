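"""Minimal reverse-mode automatic differentiation over numpy arrays.

The classifiers in this package are small, fixed-topology networks operating
on N x N connectivity matrices with N on the order of a few hundred at most,
so a lightweight tape-based engine over numpy is sufficient to train them.
Only the operations those architectures need are provided: broadcast
arithmetic, (batched) matrix products, the activations used by the models,
batch normalisation, dropout, row gathering for top-k pooling, the
cross-shaped edge filters of BrainNetCNN, and fused softmax / sigmoid
cross-entropy losses.

Gradients flow through a dynamically built DAG; ``Tensor.backward`` runs a
topological sort and accumulates ``grad`` on every tensor created with
``requires_grad=True``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast up from ``shape``."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray | float,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(other: "Tensor | np.ndarray | float") -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        """np.matmul semantics, including batched stacks of matrices."""
        other = Tensor._lift(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))
        a, b = self.data, other.data

        def backward(g):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = backward
        return out

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def transpose_last(self) -> "Tensor":
        """Swap the last two axes."""
        out = Tensor(np.swapaxes(self.data, -1, -2), parents=(self,))
        out._backward = lambda g: self._accumulate(np.swapaxes(g, -1, -2))
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: self._accumulate(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self) -> "Tensor":
        n = self.data.size
        out = Tensor(self.data.mean(), parents=(self,))
        out._backward = lambda g: self._accumulate(
            np.broadcast_to(g / n, self.data.shape)
        )
        return out

    # -- activations -------------------------------------------------------

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))
        mask = self.data > 0
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def leaky_relu(self, slope: float = 0.2) -> "Tensor":
        grad_mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * grad_mask, parents=(self,))
        out._backward = lambda g: self._accumulate(g * grad_mask)
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sigmoid(self) -> "Tensor":
        y = 0.5 * (1.0 + np.tanh(0.5 * self.data))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    # -- indexing / concatenation -----------------------------------------

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        """Per-batch row selection.

        ``self`` is (B, N, d) and ``idx`` is (B, k): returns (B, k, d) with
        out[b] = self[b, idx[b], :].  For 2-D input, plain row indexing.
        """
        idx = np.asarray(idx)
        if self.data.ndim == 2:
            out = Tensor(self.data[idx, :], parents=(self,))

            def backward2(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

            out._backward = backward2
            return out
        batch = np.arange(self.data.shape[0])[:, None]
        out = Tensor(self.data[batch, idx, :], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (batch, idx), g)
            self._accumulate(full)

        out._backward = backward
        return out

    @staticmethod
    def concat(tensors: Sequence["Tensor"], axis: int = -1) -> "Tensor":
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(
            np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors)
        )
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                t._accumulate(piece)

        out._backward = backward
        return out

    # -- stochastic / normalisation layers ---------------------------------

    def dropout(self, p: float, rng: np.random.Generator, training: bool) -> "Tensor":
        if not training or p <= 0.0:
            return self
        keep = rng.random(self.data.shape) >= p
        scale = 1.0 / (1.0 - p)
        out = Tensor(self.data * keep * scale, parents=(self,))
        out._backward = lambda g: self._accumulate(g * keep * scale)
        return out

    def batch_norm(
        self,
        gamma: "Tensor",
        beta: "Tensor",
        axes: tuple[int, ...],
        running_mean: np.ndarray,
        running_var: np.ndarray,
        training: bool,
        momentum: float = 0.9,
        eps: float = 1e-5,
    ) -> "Tensor":
        """Normalise over ``axes`` (e.g. batch and spatial dims), scale/shift
        per remaining channel.  ``running_*`` are updated in place when
        training; used directly in eval mode."""
        x = self.data
        if training:
            mean = x.mean(axis=axes, keepdims=True)
            var = x.var(axis=axes, keepdims=True)
            running_mean *= momentum
            running_mean += (1.0 - momentum) * mean
            running_var *= momentum
            running_var += (1.0 - momentum) * var
        else:
            mean, var = running_mean, running_var
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x - mean) * inv_std
        out = Tensor(
            gamma.data * xhat + beta.data, parents=(self, gamma, beta)
        )
        m = float(np.prod([x.shape[a] for a in axes])) if training else None

        def backward(g):
            gamma._accumulate(
                _unbroadcast((g * xhat), gamma.data.shape)
            )
            beta._accumulate(_unbroadcast(g, beta.data.shape))
            gxhat = g * gamma.data
            if not training:
                self._accumulate(gxhat * inv_std)
                return
            # standard batch-norm backward over the normalisation axes
            sum_gxhat = gxhat.sum(axis=axes, keepdims=True)
            sum_gxhat_xhat = (gxhat * xhat).sum(axis=axes, keepdims=True)
            gx = (inv_std / m) * (m * gxhat - sum_gxhat - xhat * sum_gxhat_xhat)
            self._accumulate(gx)

        out._backward = backward
        return out

    # -- BrainNetCNN primitives -------------------------------------------

    def edge_to_edge(self, row_w: "Tensor", col_w: "Tensor", bias: "Tensor") -> "Tensor":
        """Cross-shaped edge filter bank.

        ``self``: (B, C, N, N) input maps; ``row_w``/``col_w``: (F, C, N)
        filter weights; ``bias``: (F,).  Output (B, F, N, N) with

            out[b,f,i,j] = sum_{c,k} row_w[f,c,k] M[b,c,i,k]
                         + sum_{c,k} col_w[f,c,k] M[b,c,k,j] + bias[f]
        """
        M = self.data
        B, C, N, _ = M.shape
        F = row_w.data.shape[0]
        rw_flat = row_w.data.reshape(F, C * N)
        cw_flat = col_w.data.reshape(F, C * N)
        # rows[b,f,i] = sum_{c,k} M[b,c,i,k] rw[f,c,k]; cols via M transposed
        M_rows = M.transpose(0, 2, 1, 3).reshape(B, N, C * N)
        M_cols = M.transpose(0, 3, 1, 2).reshape(B, N, C * N)
        rows = (M_rows @ rw_flat.T).transpose(0, 2, 1)  # (B,F,N)
        cols = (M_cols @ cw_flat.T).transpose(0, 2, 1)  # (B,F,N)
        out_data = rows[:, :, :, None] + cols[:, :, None, :] + bias.data[None, :, None, None]
        out = Tensor(out_data, parents=(self, row_w, col_w, bias))

        def backward(g):
            g_rows = g.sum(axis=3).transpose(0, 2, 1)  # (B,N,F)
            g_cols = g.sum(axis=2).transpose(0, 2, 1)  # (B,N,F)
            grw = np.tensordot(g_rows, M_rows, axes=([0, 1], [0, 1]))
            gcw = np.tensordot(g_cols, M_cols, axes=([0, 1], [0, 1]))
            row_w._accumulate(grw.reshape(F, C, N))
            col_w._accumulate(gcw.reshape(F, C, N))
            bias._accumulate(g.sum(axis=(0, 2, 3)))
            gM = (g_rows @ rw_flat).reshape(B, N, C, N).transpose(0, 2, 1, 3)
            gM = gM + (g_cols @ cw_flat).reshape(B, N, C, N).transpose(0, 2, 3, 1)
            self._accumulate(gM)

        out._backward = backward
        return out

    def edge_to_node(self, w: "Tensor", bias: "Tensor") -> "Tensor":
        """Row aggregation of edges incident to each node.

        ``self``: (B, C, N, N); ``w``: (F, C, N); ``bias``: (F,).
        Output (B, F, N): out[b,f,i] = sum_{c,j} w[f,c,j] M[b,c,i,j] + bias[f].
        """
        M = self.data
        B, C, N, _ = M.shape
        F = w.data.shape[0]
        # out[b,f,i] = sum_{c,j} w[f,c,j] M[b,c,i,j], cast as BLAS matmuls
        M_flat = M.transpose(0, 2, 1, 3).reshape(B, N, C * N)  # (B, N, C*N)
        w_flat = w.data.reshape(F, C * N)
        out_data = (M_flat @ w_flat.T).transpose(0, 2, 1) + bias.data[None, :, None]
        out = Tensor(out_data, parents=(self, w, bias))

        def backward(g):
            g_bif = g.transpose(0, 2, 1)  # (B, N, F)
            gw = np.tensordot(g_bif, M_flat, axes=([0, 1], [0, 1]))  # (F, C*N)
            w._accumulate(gw.reshape(F, C, N))
            bias._accumulate(g.sum(axis=(0, 2)))
            gM = (g_bif @ w_flat).reshape(B, N, C, N).transpose(0, 2, 1, 3)
            self._accumulate(gM)

        out._backward = backward
        return out

    def node_to_graph(self, w: "Tensor", bias: "Tensor") -> "Tensor":
        """Whole-graph summarisation of per-node values.

        ``self``: (B, C, N); ``w``: (F, C, N); ``bias``: (F,).
        Output (B, F): out[b,f] = sum_{c,i} w[f,c,i] v[b,c,i] + bias[f].
        """
        v = self.data
        out = Tensor(np.einsum("bci,fci->bf", v, w.data) + bias.data[None, :],
                     parents=(self, w, bias))

        def backward(g):
            w._accumulate(np.einsum("bf,bci->fci", g, v))
            bias._accumulate(g.sum(axis=0))
            self._accumulate(np.einsum("bf,fci->bci", g, w.data))

        out._backward = backward
        return out

    # -- losses ------------------------------------------------------------

    def softmax(self) -> np.ndarray:
        """Softmax over the last axis (forward only; use the fused loss for
        gradients)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Mean softmax cross-entropy; ``labels`` are integer class ids."""
        labels = np.asarray(labels, dtype=np.intp)
        z = self.data - self.data.max(axis=-1, keepdims=True)
        logsumexp = np.log(np.exp(z).sum(axis=-1))
        picked = z[np.arange(z.shape[0]), labels]
        loss = float(np.mean(logsumexp - picked))
        out = Tensor(loss, parents=(self,))
        probs = np.exp(z - logsumexp[:, None])

        def backward(g):
            grad = probs.copy()
            grad[np.arange(grad.shape[0]), labels] -= 1.0
            self._accumulate(g * grad / grad.shape[0])

        out._backward = backward
        return out

    def binary_cross_entropy_with_logits(self, targets: np.ndarray) -> "Tensor":
        """Mean sigmoid BCE; ``targets`` in {0,1}, shape broadcastable to
        ``self``."""
        t = np.broadcast_to(np.asarray(targets, dtype=np.float64), self.data.shape)
        z = self.data
        # stable: max(z,0) - z*t + log(1+exp(-|z|))
        loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
        out = Tensor(loss, parents=(self,))
        sig = 0.5 * (1.0 + np.tanh(0.5 * z))

        def backward(g):
            self._accumulate(g * (sig - t) / z.size)

        out._backward = backward
        return out


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int | None = None, fan_out: int | None = None) -> np.ndarray:
    """Glorot/Xavier uniform initialisation."""
    if fan_in is None:
        fan_in = shape[-2] if len(shape) > 1 else shape[0]
    if fan_out is None:
        fan_out = shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimiser over a list of Tensors (bias-corrected)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
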