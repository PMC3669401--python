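"""Deterministic, hand-checkable fixture bundles.

``make_toy_bundle`` writes a tiny four-TF / ten-gene data set with two
planted co-expression blocks so the full pipeline can run offline;
``make_table1_bundle`` writes one replicate of the default simulation study
(truth triple plus noisy seeds) as edge lists.  Both are pure functions of
their seed: regenerating reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass

import numpy as np

from .netio import LabeledBipartiteNetwork, LabeledSymmetricNetwork, write_network
from .simulate import NoiseSpec, make_noisy_seeds, simulate_truth

__all__ = ["FixtureBundle", "make_toy_bundle", "make_table1_bundle"]


@dataclass
class FixtureBundle:
    name: str
    seed: int
    manifest: dict[str, str]  # path -> sha256

    def checksum(self) -> str:
        h = hashlib.sha256()
        for path in sorted(self.manifest):
            h.update(self.manifest[path].encode())
        return h.hexdigest()


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()


def _write_lines(path, lines) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def make_toy_bundle(seed: int = 0, out_dir: str = ".") -> FixtureBundle:
    """Write a 4-TF x 10-gene toy data set with two planted modules.

    TF1/TF2 drive genes g01-g05 (block A), TF3/TF4 drive g06-g10 (block B);
    expression has 8 samples with strong within-block correlation (pairwise
    r > 0.8 by construction), the PPI table links the within-block TF pairs,
    and the gold standard is the planted regulatory structure.  The prior is
    the truth with one block-A edge removed and one spurious cross-block edge
    added, so refinement has something to recover.
    """
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    tfs = ["TF1", "TF2", "TF3", "TF4"]
    genes = [f"g{j:02d}" for j in range(1, 11)]
    block_a, block_b = genes[:5], genes[5:]

    true_edges = [(t, g) for t in ("TF1", "TF2") for g in block_a] + [
        (t, g) for t in ("TF3", "TF4") for g in block_b
    ]
    prior_edges = [e for e in true_edges if e != ("TF1", "g02")] + [("TF1", "g08")]

    _write_lines(
        os.path.join(out_dir, "prior.tsv"), [f"{t}\t{g}\t1" for t, g in prior_edges]
    )
    _write_lines(
        os.path.join(out_dir, "ppi.tsv"), ["TF1\tTF2\t1", "TF3\tTF4\t1"]
    )
    _write_lines(
        os.path.join(out_dir, "gold.tsv"), [f"{t}\t{g}\t1" for t, g in true_edges]
    )

    samples = [f"s{k}" for k in range(1, 9)]
    base_a = rng.normal(0.0, 1.0, size=8)
    base_b = rng.normal(0.0, 1.0, size=8)
    expr_rows = ["gene\t" + "\t".join(samples)]
    for g in genes:
        base = base_a if g in block_a else base_b
        profile = base + rng.normal(0.0, 0.15, size=8)  # noise sd keeps r > 0.8
        expr_rows.append(g + "\t" + "\t".join(f"{v:.6f}" for v in profile))
    _write_lines(os.path.join(out_dir, "expression.tsv"), expr_rows)

    manifest = {
        f: _sha256(os.path.join(out_dir, f))
        for f in ("prior.tsv", "ppi.tsv", "expression.tsv", "gold.tsv")
    }
    return FixtureBundle(name="toy", seed=seed, manifest=manifest)


def make_table1_bundle(seed: int = 0, out_dir: str = ".") -> FixtureBundle:
    """Write one replicate of the default simulation (truth + noisy seeds)."""
    os.makedirs(out_dir, exist_ok=True)
    truth = simulate_truth(seed=seed)
    seeds = make_noisy_seeds(truth, NoiseSpec(), seed=seed + 1)
    nets = {
        "truth_regulatory.txt": LabeledBipartiteNetwork(
            truth.tf_labels, truth.gene_labels, truth.W_true
        ),
        "truth_cooperativity.txt": LabeledSymmetricNetwork(truth.tf_labels, truth.P_true),
        "truth_coregulation.txt": LabeledSymmetricNetwork(truth.gene_labels, truth.C_true),
        "noisy_regulatory.txt": seeds.regulatory,
        "noisy_cooperativity.txt": seeds.cooperativity,
        "noisy_coregulation.txt": seeds.coregulation,
    }
    for fname, net in nets.items():
        write_network(net, os.path.join(out_dir, fname), format="edge-list")
    manifest = {f: _sha256(os.path.join(out_dir, f)) for f in nets}
    return FixtureBundle(name="table1", seed=seed, manifest=manifest)
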