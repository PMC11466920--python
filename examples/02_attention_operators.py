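"""The three attention operators and their analytic cost.

Runs window attention with the window covering the whole grid and checks it
against a dense softmax-attention evaluation, then prints the multiplication
counts of window attention, global spatial attention (GSA), and global
channel attention (GCA) for a bottleneck-sized feature map.  GCA is always
cheaper than GSA by exactly 2hwC^2 multiplications because it skips two of
the four channel-sized projections.
"""

import numpy as np

from duoseg import complexity_report
from duoseg.encoders import WindowAttention
from duoseg.nn import Tensor, seed_all

seed_all(0)
rng = np.random.default_rng(0)

attn = WindowAttention(dim=16, heads=4, window=4, rel_pos_bias=False)
x = rng.normal(size=(1, 16, 16))  # one 4x4 window of 16-dim tokens
out = attn(Tensor(x)).data

# dense oracle on the same projections
qkv = x @ attn.qkv.weight.data.T + attn.qkv.bias.data
q, k, v = np.split(qkv, 3, axis=-1)
dh = 4
dense = np.zeros_like(x)
for h in range(4):
    sl = slice(h * dh, (h + 1) * dh)
    logits = q[0][:, sl] @ k[0][:, sl].T / np.sqrt(dh)
    a = np.exp(logits - logits.max(axis=-1, keepdims=True))
    a /= a.sum(axis=-1, keepdims=True)
    dense[0][:, sl] = a @ v[0][:, sl]
dense = dense @ attn.proj.weight.data.T + attn.proj.bias.data
print(f"max |window attention - dense oracle| = {np.abs(out - dense).max():.2e}")

report = complexity_report(h=16, w=16, channels=128, window=8)
print(f"multiplications on a 16x16x128 map (window 8):")
print(f"  window attention: {report.flops_wmsa:,}")
print(f"  GSA:              {report.flops_gsa:,}")
print(f"  GCA:              {report.flops_gca:,}  (cheaper by 2hwC^2 = {2*16*16*128**2:,})")
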