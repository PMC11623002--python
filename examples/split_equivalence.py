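"""The split-training exchange computes centralized gradients.

Runs one batch through client-forward -> server-step -> client-backward
and through the composed model, then prints the worst relative gradient
difference over all parameters. The split protocol changes where
computation happens, not what is computed.
"""

import numpy as np

from splitfed import nn
from splitfed.models import (ClientNet, ServerNet, compose, forward_client,
                             server_step, client_backward)
from splitfed.phantom import PhantomSpec, generate_phantom_dataset

ds = generate_phantom_dataset(
    PhantomSpec(image_size=32, n_per_class=(8, 8, 8), seed=1))
x = np.stack(ds.images[:12])[:, None]
y = ds.labels[:12]

cl_a, sv_a = ClientNet(0.25, dropout=0.0, seed=1), ServerNet(0.25, seed=2)
cl_b, sv_b = ClientNet(0.25, dropout=0.0, seed=1), ServerNet(0.25, seed=2)

smashed = forward_client(cl_a, x, y)
print("smashed data:", smashed.activations.shape, "labels shared:", len(y))
packet = server_step(sv_a, smashed, train=True)
client_backward(cl_a, smashed, packet)
print("loss at the server:", round(packet.loss, 6))

model = compose(cl_b, sv_b)
loss, _ = nn.softmax_cross_entropy(model(x), y)
model.zero_grad()
loss.backward()
print("composed-model loss:", round(loss.item(), 6))

worst = max(
    float(np.abs(pa.grad - pb.grad).max() / (np.abs(pb.grad).max() + 1e-30))
    for pa, pb in zip(list(cl_a.parameters()) + list(sv_a.parameters()),
                      list(cl_b.parameters()) + list(sv_b.parameters())))
print("worst relative gradient difference:", worst)
# Expected: identical losses and a worst relative difference of 0.0 —
# both paths execute the same arithmetic in the same order.
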