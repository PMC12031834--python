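"""Phase transfer entropy and graph metrics vs independent brute-force oracles."""
from collections import Counter

import numpy as np
import pytest

from icans_qeeg.connectivity import (PTEMatrix, default_delay, graph_metrics,
                                     instantaneous_phase, pte_matrix, pte_pair)
from icans_qeeg.exceptions import ConfigError, DataError, SizeError
from icans_qeeg.preprocess import apply_filters, assemble_epoch
from icans_qeeg.records import Epoch
from icans_qeeg.simulate import EEGSimSpec, simulate_eeg

FS = 256.0


class TestInstantaneousPhase:
    def test_tone_phase_increment(self):
        f = 10.0
        x = np.sin(2 * np.pi * f * np.arange(2560) / FS)
        ph = instantaneous_phase(x)
        inc = np.diff(np.unwrap(ph))[100:-100]
        assert np.allclose(inc, 2 * np.pi * f / FS, rtol=0.01)

    def test_sign_flip_shifts_by_pi(self):
        x = np.sin(2 * np.pi * 8 * np.arange(2560) / FS)
        d = np.angle(np.exp(1j * (instantaneous_phase(-x) - instantaneous_phase(x))))
        assert np.allclose(np.abs(d[100:-100]), np.pi, atol=0.05)

    def test_constant_signal_degenerate(self):
        with pytest.raises(DataError):
            instantaneous_phase(np.ones(512))


def _bin_phase(p, nb):
    return np.clip(np.floor((p + np.pi) / (2 * np.pi) * nb).astype(int), 0, nb - 1)


def brute_pte(phase_x, phase_y, delay, n_bins):
    """Independent triple-histogram counting implementation."""
    bx, by = _bin_phase(phase_x, n_bins), _bin_phase(phase_y, n_bins)
    yf, yp, xp = by[delay:], by[:-delay], bx[:-delay]
    n = len(yf)
    c3 = Counter(zip(yf, yp, xp))
    c_yx = Counter(zip(yp, xp))
    c_yy = Counter(zip(yf, yp))
    c_y = Counter(yp)
    te = 0.0
    for (a, b, c), cnt in c3.items():
        te += cnt / n * np.log((cnt / c_yx[(b, c)]) / (c_yy[(a, b)] / c_y[b]))
    return te


class TestPTEPair:
    def test_matches_brute_force_on_toys(self, rng):
        for _ in range(10):
            px = rng.uniform(-np.pi, np.pi, 500)
            py = rng.uniform(-np.pi, np.pi, 500)
            mine = pte_pair(px, py, delay=5, n_bins=6)
            assert mine == pytest.approx(brute_pte(px, py, 5, 6), abs=1e-10)

    def test_nonnegative_and_null_contrast(self):
        # independent phases: PTE is pure estimator bias, symmetric in
        # direction, so the directional contrast averages to ~0
        contrasts, ptes = [], []
        for seed in range(100):
            r = np.random.default_rng(seed)
            px = r.uniform(-np.pi, np.pi, 2000)
            py = r.uniform(-np.pi, np.pi, 2000)
            a = pte_pair(px, py, delay=5, n_bins=8)
            b = pte_pair(py, px, delay=5, n_bins=8)
            ptes += [a, b]
            contrasts.append(a - b)
        assert min(ptes) >= -1e-9
        assert abs(np.mean(contrasts)) < 3 * np.std(contrasts) / 10  # 3 SE
        assert abs(np.mean(contrasts)) < 0.2 * np.mean(ptes)

    def test_directed_coupling_detected(self, rng):
        hits = 0
        for _ in range(40):
            px = rng.uniform(-np.pi, np.pi, 3000)
            delay = 4
            py = np.roll(px, delay)  # y is x delayed
            if pte_pair(px, py, delay=delay, n_bins=8) > \
               pte_pair(py, px, delay=delay, n_bins=8):
                hits += 1
        assert hits >= 38

    def test_short_series_error(self):
        with pytest.raises(SizeError):
            pte_pair(np.zeros(5), np.zeros(5), delay=6, n_bins=4)

    def test_bad_bins(self):
        with pytest.raises(ConfigError):
            pte_pair(np.zeros(100), np.zeros(100), delay=2, n_bins=1)


class TestPTEMatrix:
    def _epoch(self, seed=0, n_ch=3, duration=20.0):
        spec = EEGSimSpec(n_channels=n_ch, duration=duration, seed=seed,
                          channel_labels=("F3", "Cz", "P4")[:n_ch])
        record, _ = simulate_eeg(spec)
        return assemble_epoch(apply_filters(record), [])

    def test_shape_and_zero_diagonal(self):
        m = pte_matrix(self._epoch())
        assert m.values.shape == (3, 3)
        assert np.all(np.diag(m.values) == 0)
        assert np.all(m.values >= -1e-9)

    def test_two_channels_two_entries(self):
        ep = self._epoch(n_ch=2)
        m = pte_matrix(ep)
        assert (m.values != 0).sum() == 2

    def test_channel_permutation_equivariance(self):
        ep = self._epoch()
        m = pte_matrix(ep, delay=8, n_bins=8).values
        perm = [2, 0, 1]
        ep2 = Epoch(ep.signal[perm], ep.fs,
                    channel_labels=tuple(ep.channel_labels[i] for i in perm))
        m2 = pte_matrix(ep2, delay=8, n_bins=8).values
        assert np.allclose(m2, m[np.ix_(perm, perm)], atol=1e-12)

    def test_driver_identified_on_coupled_pair(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            spec = EEGSimSpec(n_channels=2, duration=60.0, seed=seed,
                              channel_labels=("C3", "C4"),
                              couplings=((0, 1, 20, 1.0),),
                              band_amplitudes={"alpha": 5.0, "theta": 2.0},
                              pink_noise_amp=2.0)
            record, _ = simulate_eeg(spec)
            ep = assemble_epoch(apply_filters(record), [])
            m = pte_matrix(ep).values
            if m[0, 1] > m[1, 0]:
                hits += 1
        assert hits >= 22


# --- brute-force graph oracle -------------------------------------------------

def brute_graph(w):
    """All-pairs shortest paths by Floyd-Warshall with path counting,
    betweenness by explicit path enumeration, eigenvector by power iteration."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    nxt = [[set() for _ in range(n)] for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                dist[i, j] = 1.0 / w[i, j]
                nxt[i][j] = {j}
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j] - 1e-12:
                    dist[i, j] = dist[i, k] + dist[k, j]

    def count_paths(s, t):
        """(number of shortest s->t paths, count passing through each node)."""
        if not np.isfinite(dist[s, t]) or s == t:
            return 0, np.zeros(n)
        total = 0
        through = np.zeros(n)
        stack = [(s, 0.0, [s])]
        while stack:
            node, d, path = stack.pop()
            if node == t:
                total += 1
                for v in path[1:-1]:
                    through[v] += 1
                continue
            for j in range(n):
                if j != node and w[node, j] > 0:
                    nd = d + 1.0 / w[node, j]
                    if abs(nd + dist[j, t] - dist[s, t]) < 1e-9 and j not in path:
                        stack.append((j, nd, path + [j]))
        return total, through

    btw = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            total, through = count_paths(s, t)
            if total:
                btw += through / total

    ecc = np.full(n, np.inf)
    if np.all(np.isfinite(dist[~np.eye(n, dtype=bool)])):  # strongly connected
        for i in range(n):
            ecc[i] = max(dist[i, j] for j in range(n) if j != i)
    diam = ecc.max() if np.all(np.isfinite(ecc)) else np.inf

    # eigenvector centrality on in-edges: x <- W^T x
    x = np.ones(n)
    for _ in range(2000):
        x_new = w.T @ x
        if x_new.max() == 0:
            break
        x_new = x_new / np.linalg.norm(x_new)
        if np.allclose(x_new, x, atol=1e-14):
            x = x_new
            break
        x = x_new
    eig = np.abs(x) / np.abs(x).max() if x.max() > 0 else np.zeros(n)
    return dict(in_deg=w.sum(0), out_deg=w.sum(1), btw=btw, ecc=ecc,
                diam=diam, eig=eig)


class TestGraphMetrics:
    def test_directed_three_cycle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 2] = w[2, 0] = 1.0
        gm = graph_metrics(PTEMatrix(w, ("a", "b", "c")))
        assert np.allclose(gm.eccentricity, 2.0)
        assert gm.diameter == 2.0
        assert np.allclose(gm.betweenness, 1.0)
        assert np.allclose(gm.eigenvector, 1.0)

    def test_out_star(self):
        n = 5
        w = np.zeros((n, n))
        w[0, 1:] = 1.0
        gm = graph_metrics(PTEMatrix(w, tuple("abcde")))
        assert gm.out_degree[0] == n - 1
        assert gm.in_degree[0] == 0
        assert not np.isfinite(gm.diameter)  # not strongly connected

    def test_random_digraphs_match_brute_force(self, rng):
        for trial in range(100):
            n = int(rng.integers(3, 7))
            w = rng.uniform(0.2, 2.0, (n, n)) * (rng.random((n, n)) < 0.6)
            np.fill_diagonal(w, 0.0)
            gm = graph_metrics(PTEMatrix(w, tuple(f"ch{i}" for i in range(n))))
            ref = brute_graph(w)
            assert np.allclose(gm.in_degree, ref["in_deg"])
            assert np.allclose(gm.out_degree, ref["out_deg"])
            assert np.allclose(gm.betweenness, ref["btw"], atol=1e-8), trial
            same_inf = np.isfinite(gm.eccentricity) == np.isfinite(ref["ecc"])
            assert same_inf.all()
            finite = np.isfinite(gm.eccentricity)
            assert np.allclose(gm.eccentricity[finite], ref["ecc"][finite])
            if np.isfinite(gm.diameter) or np.isfinite(ref["diam"]):
                assert gm.diameter == pytest.approx(ref["diam"])
            vals = np.abs(np.linalg.eigvals(w))
            vals.sort()
            gap_ok = vals[-1] > 0 and (len(vals) < 2 or vals[-2] < 0.999 * vals[-1])
            if (w.sum(0) > 0).all() and gap_ok:  # power iteration well-defined
                assert np.allclose(gm.eigenvector, ref["eig"], atol=1e-5)

    def test_permutation_equivariance(self, rng):
        w = rng.uniform(0.1, 1.0, (4, 4))
        np.fill_diagonal(w, 0.0)
        labels = ("w", "x", "y", "z")
        gm = graph_metrics(PTEMatrix(w, labels))
        perm = [3, 1, 0, 2]
        gm2 = graph_metrics(PTEMatrix(w[np.ix_(perm, perm)],
                                      tuple(labels[i] for i in perm)))
        assert np.allclose(gm2.in_degree, gm.in_degree[perm])
        assert np.allclose(gm2.betweenness, gm.betweenness[perm])
        assert np.allclose(gm2.eccentricity, gm.eccentricity[perm])
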