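"""Directed connectivity: broadband PTE matrix and graph measures.

Simulates a 19-channel record with a known frontal->posterior coupling,
computes the phase-transfer-entropy matrix on the assembled epoch, derives the
weighted-digraph measures, and checks that on each coupled pair the PTE
asymmetry points from the injected driver to its target.
"""
from pathlib import Path

import pandas as pd

from icans_qeeg.connectivity import graph_metrics, pte_matrix
from icans_qeeg.preprocess import apply_filters, assemble_epoch
from icans_qeeg.records import CHANNELS_1020
from icans_qeeg.simulate import EEGSimSpec, simulate_eeg

RESULTS = Path("results")
SEED = 1
DRIVER = CHANNELS_1020.index("Fz")
TARGETS = [CHANNELS_1020.index(ch) for ch in ("Pz", "O1", "O2")]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = EEGSimSpec(
        duration=60.0, seed=SEED,
        couplings=tuple((DRIVER, t, 20, 1.0) for t in TARGETS),
    )
    record, _ = simulate_eeg(spec)
    epoch = assemble_epoch(apply_filters(record), [])

    ptem = pte_matrix(epoch)
    pd.DataFrame(ptem.values, index=ptem.channel_labels,
                 columns=ptem.channel_labels).to_csv(RESULTS / "pte_matrix.csv")

    gm = graph_metrics(ptem)
    metrics = pd.DataFrame({
        "channel": gm.channel_labels,
        "in_degree": gm.in_degree, "out_degree": gm.out_degree,
        "betweenness": gm.betweenness, "eigenvector": gm.eigenvector,
        "eccentricity": gm.eccentricity,
    })
    metrics.to_csv(RESULTS / "graph_metrics.csv", index=False)

    print("PTE asymmetry on the injected couplings (driver -> target):")
    labels = list(ptem.channel_labels)
    for t in TARGETS:
        fwd = ptem.values[DRIVER, t]
        rev = ptem.values[t, DRIVER]
        mark = "ok" if fwd > rev else "MISSED"
        print(f"  {labels[DRIVER]}->{labels[t]}: {fwd:.3f} vs reverse "
              f"{rev:.3f}  [{mark}]")
    net = gm.out_degree - gm.in_degree
    print(f"net outflow of {labels[DRIVER]}: {net[DRIVER]:.3f} "
          f"(cohort-level graph summaries in graph_metrics.csv); "
          f"graph diameter: {gm.diameter:.2f}")
    print(f"wrote {RESULTS/'pte_matrix.csv'} and {RESULTS/'graph_metrics.csv'}")


if __name__ == "__main__":
    main()
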