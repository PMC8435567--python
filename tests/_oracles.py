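"""Independent numpy-only reference evaluations used as test oracles.

These re-derive each attention/loss computation directly from the layer
weight arrays with plain loops/numpy, sharing no code with the package's
autodiff path.
"""

import numpy as np

EPS = 1e-5


def depthwise_conv(x, w, pad):
    """x (N,C,H,W), w (C,1,k,k) -> same-size depthwise cross-correlation."""
    n, c, h, wd = x.shape
    k = w.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    out = np.zeros_like(x)
    for i in range(h):
        for j in range(wd):
            patch = xp[:, :, i:i + k, j:j + k]
            out[:, :, i, j] = (patch * w[:, 0]).sum(axis=(2, 3))
    return out


def conv2d_full(x, w, stride=1, pad=0, bias=None):
    """Plain (groups=1) cross-correlation by explicit loops."""
    n, cin, h, wd = x.shape
    cout, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (wd + 2 * pad - k) // stride + 1
    out = np.zeros((n, cout, ho, wo))
    for o in range(cout):
        for i in range(ho):
            for j in range(wo):
                patch = xp[:, :, i * stride:i * stride + k, j * stride:j * stride + k]
                out[:, o, i, j] = (patch * w[o]).sum(axis=(1, 2, 3))
    if bias is not None:
        out += bias.reshape(1, -1, 1, 1)
    return out


def bn_eval(x, bn):
    """Eval-mode batch norm from running statistics; NCHW or NC input."""
    g, b = bn.gamma.data, bn.beta.data
    m, v = bn.running_mean, bn.running_var
    if x.ndim == 4:
        shape = (1, -1, 1, 1)
    else:
        shape = (1, -1)
    return ((x - m.reshape(shape)) / np.sqrt(v.reshape(shape) + bn.eps)
            ) * g.reshape(shape) + b.reshape(shape)


def standardize(v, axis, eps=EPS):
    mu = v.mean(axis=axis, keepdims=True)
    var = v.var(axis=axis, keepdims=True)
    return (v - mu) / np.sqrt(var + eps)


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def softmax(z, axis=-1):
    e = np.exp(z - z.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def sge(y, gamma, beta, groups, eps=EPS):
    n, c, h, w = y.shape
    yg = y.reshape(n, groups, c // groups, h, w)
    gd = yg.mean(axis=(3, 4), keepdims=True)
    sim = (yg * gd).sum(axis=2)
    shat = standardize(sim.reshape(n, groups, -1), axis=2, eps=eps).reshape(n, groups, h, w)
    gate = sigmoid(shat * gamma.reshape(1, -1, 1, 1) + beta.reshape(1, -1, 1, 1))
    return (yg * gate[:, :, None]).reshape(n, c, h, w)


def ska(x, module):
    """Sequential divide/fuse/aggregation evaluation of an eval-mode SKA
    module, entirely in numpy from its weight arrays."""
    cfg = module.cfg

    def branch(xx, br):
        z = depthwise_conv(xx, br.conv.weight.data, (br.kernel - 1) // 2)
        return np.maximum(bn_eval(z, br.bn), 0.0)

    y1 = branch(x, module.branch_a)
    y2 = branch(x, module.branch_b)
    n, c = x.shape[0], x.shape[1]
    g = standardize((y1 + y2).mean(axis=(2, 3)), axis=1)
    g_grp = g.reshape(n, cfg.groups, c // cfg.groups).mean(axis=2)
    g1 = np.maximum(bn_eval(g_grp @ module.fuse.fc.weight.data, module.fuse.bn), 0.0)
    if module.use_sge:
        y1 = sge(y1, module.sge_a.gamma.data, module.sge_a.beta.data, cfg.groups)
        y2 = sge(y2, module.sge_b.gamma.data, module.sge_b.beta.data, cfg.groups)
    logits = g1 @ module.select.head.weight.data + module.select.head.bias.data
    v = softmax(logits, axis=1)
    return v[:, 0, None, None, None] * y1 + v[:, 1, None, None, None] * y2


def cbam(f, module):
    """Channel-then-spatial gating from the CBAM layer's weight arrays."""
    n, c, h, w = f.shape

    def mlp(v):
        hidden = np.maximum(v @ module.mlp1.weight.data + module.mlp1.bias.data, 0.0)
        return hidden @ module.mlp2.weight.data + module.mlp2.bias.data

    avg = f.mean(axis=(2, 3))
    mx = f.reshape(n, c, -1).max(axis=2)
    mc = sigmoid(mlp(avg) + mlp(mx))
    fc = f * mc[:, :, None, None]
    sp = np.stack([fc.mean(axis=1), fc.max(axis=1)], axis=1)
    ms = sigmoid(conv2d_full(sp, module.spatial.weight.data, pad=3,
                             bias=module.spatial.bias.data))
    return fc * ms


def kl(pa, pb, eps=1e-8):
    pa, pb = np.asarray(pa, float), np.asarray(pb, float)
    return float((pa * (np.log(pa + eps) - np.log(pb + eps))).sum(axis=1).mean())


def cross_entropy_mean_heads(p3, p4, p, labels, eps=1e-8):
    mean = (np.asarray(p3) + np.asarray(p4) + np.asarray(p)) / 3.0
    rows = mean[np.arange(len(labels)), labels]
    return float(-np.log(rows + eps).mean())
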