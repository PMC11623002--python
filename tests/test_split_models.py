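"""Split network: shapes, compose identity, and the split-equivalence oracle."""

import numpy as np
import pytest

from splitfed import nn
from splitfed.data import DatasetError
from splitfed.models import (ClientNet, ServerNet, SmashedBatch, compose,
                             forward_client, server_step, client_backward)
from splitfed.phantom import PhantomSpec, generate_phantom_dataset


def phantom_batch(n=8, size=32, seed=3):
    ds = generate_phantom_dataset(
        PhantomSpec(image_size=size, n_per_class=(n, n, n), seed=seed))
    idx = np.concatenate([np.flatnonzero(ds.labels == c)[: n // 2]
                          for c in range(3)])
    x = np.stack([ds.images[i] for i in idx])[:, None].astype(np.float32)
    return x, ds.labels[idx]


class TestShapes:
    def test_cut_activations_quarter_resolution_224(self):
        net = ClientNet(width=1.0, dropout=0.0, seed=0)
        x = np.random.default_rng(0).random((2, 1, 224, 224)).astype(np.float32)
        sm = forward_client(net, x, np.array([0, 1]))
        assert sm.activations.shape == (2, 64, 56, 56)
        assert np.array_equal(sm.labels, [0, 1])

    def test_indivisible_size_rejected(self):
        net = ClientNet(width=0.25, seed=0)
        with pytest.raises(DatasetError):
            forward_client(net, np.zeros((1, 1, 30, 30), dtype=np.float32),
                           np.array([0]))

    def test_eval_forward_deterministic_despite_dropout(self):
        net = ClientNet(width=0.25, dropout=0.5, seed=0)
        net.eval()
        x, y = phantom_batch()
        a = forward_client(net, x, y).activations
        b = forward_client(net, x, y).activations
        assert np.array_equal(a, b)

    def test_server_output_is_n_classes(self):
        server = ServerNet(width=0.25, n_classes=3, seed=1)
        out = server(np.random.default_rng(0).random((2, 16, 8, 8)).astype(np.float32))
        assert out.shape == (2, 3)


class TestServerStep:
    def test_uniform_predictions_loss_ln3(self):
        server = ServerNet(width=0.25, n_classes=3, seed=1)
        server.fc.weight.data[...] = 0.0
        server.fc.bias.data[...] = 0.0
        sm = SmashedBatch(
            activations=np.random.default_rng(0).random((6, 16, 8, 8)).astype(np.float32),
            labels=np.array([0, 1, 2, 0, 1, 2]))
        pkt = server_step(server, sm, train=False)
        assert pkt.loss == pytest.approx(np.log(3), abs=1e-6)
        assert pkt.grad is None

    def test_gradient_shape_matches_smashed(self):
        server = ServerNet(width=0.25, n_classes=3, seed=1)
        sm = SmashedBatch(
            activations=np.random.default_rng(0).random((4, 16, 8, 8)).astype(np.float32),
            labels=np.array([0, 1, 2, 0]))
        pkt = server_step(server, sm, train=True)
        assert pkt.grad.shape == sm.activations.shape
        assert pkt.predictions.shape == (4, 3)

    def test_label_out_of_range(self):
        server = ServerNet(width=0.25, n_classes=3, seed=1)
        sm = SmashedBatch(activations=np.zeros((1, 16, 8, 8), dtype=np.float32),
                          labels=np.array([7]))
        with pytest.raises(ValueError):
            server_step(server, sm, train=False)


class TestClientBackward:
    def test_zero_gradient_packet_is_exact_noop_with_fresh_adam(self):
        client = ClientNet(width=0.25, dropout=0.0, seed=0)
        opt = nn.Adam(client.parameters(), lr=1e-2)
        x, y = phantom_batch()
        sm = forward_client(client, x, y)
        before = client.state_dict()
        from splitfed.models import GradientPacket
        pkt = GradientPacket(grad=np.zeros_like(sm.activations), loss=0.0,
                             predictions=np.zeros((len(y), 3)))
        client_backward(client, sm, pkt, opt)
        after = client.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_shape_mismatch_rejected(self):
        client = ClientNet(width=0.25, dropout=0.0, seed=0)
        x, y = phantom_batch()
        sm = forward_client(client, x, y)
        from splitfed.models import GradientPacket
        bad = GradientPacket(grad=np.zeros((1, 2, 3, 4)), loss=0.0,
                             predictions=None)
        with pytest.raises(DatasetError):
            client_backward(client, sm, bad, None)

    def test_repeated_steps_decrease_loss_on_fixed_batch(self):
        client = ClientNet(width=0.25, dropout=0.0, seed=2)
        server = ServerNet(width=0.25, n_classes=3, seed=3)
        opt_c = nn.Adam(client.parameters(), lr=1e-4)
        opt_s = nn.Adam(server.parameters(), lr=1e-4)
        x, y = phantom_batch(n=8)
        losses = []
        for _ in range(6):
            sm = forward_client(client, x, y)
            pkt = server_step(server, sm, train=True, optimizer=opt_s)
            client_backward(client, sm, pkt, opt_c)
            losses.append(pkt.loss)
        assert all(b < a for a, b in zip(losses, losses[1:]))


class TestCompose:
    def test_composed_equals_two_stage_path(self):
        client = ClientNet(width=0.25, dropout=0.0, seed=4)
        server = ServerNet(width=0.25, n_classes=3, seed=5)
        model = compose(client, server)
        model.eval()
        x, y = phantom_batch()
        sm = forward_client(client, x, y)
        two_stage = server(sm.activations).data
        composed = model(x).data
        assert np.array_equal(two_stage, composed)

    def test_parameter_count_is_sum_of_halves(self):
        client = ClientNet(width=0.25, seed=0)
        server = ServerNet(width=0.25, seed=1)
        model = compose(client, server)
        assert model.num_parameters() == \
            client.num_parameters() + server.num_parameters()

    def test_incompatible_widths_rejected(self):
        with pytest.raises(DatasetError):
            compose(ClientNet(width=0.25, seed=0), ServerNet(width=0.5, seed=0))

    def test_weights_shared_not_copied(self):
        client = ClientNet(width=0.25, seed=0)
        server = ServerNet(width=0.25, seed=1)
        model = compose(client, server)
        client.conv1.weight.data[...] = 1.5
        assert np.all(model.client.conv1.weight.data == 1.5)


class TestSplitEquivalence:
    """Core correctness property: gradients via the split exchange equal the
    composed-model backpropagation for every parameter."""

    @pytest.mark.parametrize("train_mode", [True, False], ids=["bn-train", "bn-eval"])
    def test_gradients_match(self, train_mode):
        x, y = phantom_batch(n=8)
        cl_a = ClientNet(width=0.25, dropout=0.0, seed=5)
        sv_a = ServerNet(width=0.25, n_classes=3, seed=6)
        cl_b = ClientNet(width=0.25, dropout=0.0, seed=5)
        sv_b = ServerNet(width=0.25, n_classes=3, seed=6)
        model = compose(cl_b, sv_b)
        if not train_mode:
            for m in (cl_a, sv_a):
                m.eval()
            model.eval()

        sm = forward_client(cl_a, x, y)
        pkt = server_step(sv_a, sm, train=True, optimizer=None)
        client_backward(cl_a, sm, pkt, None)

        loss, _ = nn.softmax_cross_entropy(model(x), y)
        model.zero_grad()
        loss.backward()

        assert pkt.loss == pytest.approx(loss.item(), rel=1e-6)
        pairs = zip(list(cl_a.named_parameters()) + list(sv_a.named_parameters()),
                    list(cl_b.named_parameters()) + list(sv_b.named_parameters()))
        for (name, pa), (_, pb) in pairs:
            denom = np.abs(pb.grad).max() + 1e-30
            rel = np.abs(pa.grad - pb.grad).max() / denom
            assert rel <= 1e-5, name

    def test_batchnorm_running_stats_update_identically(self):
        x, y = phantom_batch(n=8)
        cl_a = ClientNet(width=0.25, dropout=0.0, seed=5)
        cl_b = ClientNet(width=0.25, dropout=0.0, seed=5)
        forward_client(cl_a, x, y)
        forward_client(cl_b, x, y)
        for (na, ba), (_, bb) in zip(cl_a.named_buffers(), cl_b.named_buffers()):
            assert np.array_equal(ba, bb), na
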