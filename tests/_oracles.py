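"""Independent scalar-loop oracles for the objective terms and small networks.

Everything here is written with explicit Python loops and the math module —
no shared code with the package — so agreement is evidence of correctness,
not tautology.
"""

import math


def triplet_loss_oracle(z_a, z_p, z_n, margin):
    """Σ_i ‖z_a−z_p‖² + max(0, m − ‖z_a−z_n‖²), plain loops."""
    total = 0.0
    for a, p, nn in zip(z_a, z_p, z_n):
        d_pos = sum((ai - pi) ** 2 for ai, pi in zip(a, p))
        d_neg = sum((ai - ni) ** 2 for ai, ni in zip(a, nn))
        total += d_pos + max(0.0, margin - d_neg)
    return total


def gen_adv_oracle(s_a, s_p, s_n):
    """−(1/3) Σ_roles mean_i min(0, −1 + s_i)."""
    total = 0.0
    for scores in (s_a, s_p, s_n):
        total += sum(min(0.0, -1.0 + s) for s in scores) / len(scores)
    return -total / 3.0


def disc_oracle(real_roles, fake_roles):
    """(1/6) Σ over six role-terms of mean hinge."""
    total = 0.0
    for scores in real_roles:
        total += sum(max(0.0, 1.0 - s) for s in scores) / len(scores)
    for scores in fake_roles:
        total += sum(max(0.0, 1.0 + s) for s in scores) / len(scores)
    return total / 6.0


def cycle_oracle(originals, reconstructions):
    """(1/3) Σ_roles Σ_i Σ_j |recon_ij − orig_ij|."""
    total = 0.0
    for orig, rec in zip(originals, reconstructions):
        for o_row, r_row in zip(orig, rec):
            total += sum(abs(r - o) for o, r in zip(o_row, r_row))
    return total / 3.0


def linear_oracle(x, W, b):
    n_out = len(b)
    return [sum(x[i] * W[i][j] for i in range(len(x))) + b[j] for j in range(n_out)]


def leaky_oracle(v, slope):
    return [vi if vi > 0 else slope * vi for vi in v]


def conv_same_oracle(grid, w, b, slope):
    """One same-padded conv layer + Leaky ReLU on a (C_in, L) grid of lists."""
    c_out = len(w)
    c_in = len(grid)
    L = len(grid[0])
    k = len(w[0][0])
    pad = (k - 1) // 2
    out = []
    for o in range(c_out):
        row = []
        for pos in range(L):
            acc = b[o]
            for i in range(c_in):
                for j in range(k):
                    src = pos - pad + j
                    if 0 <= src < L:
                        acc += w[o][i][j] * grid[i][src]
            row.append(acc if acc > 0 else slope * acc)
        out.append(row)
    return out


def gan_net_oracle(x, params, channels, L, slope):
    """Scalar-loop replay of the generator/discriminator layer chain."""
    W, b = params["lin_in"]["W"].tolist(), params["lin_in"]["b"].tolist()
    h = linear_oracle(list(x), W, b)
    grid = [h[c * L:(c + 1) * L] for c in range(channels[0])]
    for conv, (c_in, c_out) in zip(params["convs"], zip(channels, channels[1:])):
        grid = conv_same_oracle(grid, conv["w"].tolist(), conv["b"].tolist(), slope)
    flat = [v for row in grid for v in row]
    return linear_oracle(flat, params["lin_out"]["W"].tolist(),
                         params["lin_out"]["b"].tolist())


def reduction_head_oracle(x, head_params, slope):
    h = list(x)
    for li, layer in enumerate(head_params):
        h = linear_oracle(h, layer["W"].tolist(), layer["b"].tolist())
        if li < 2:
            h = leaky_oracle(h, slope)
    return h


def softmax_oracle(scores):
    m = max(scores)
    exps = [math.exp(s - m) for s in scores]
    z = sum(exps)
    return [e / z for e in exps]
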