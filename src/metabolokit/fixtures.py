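"""Seeded synthetic-data generators.

These emulate a GC-TOF-MS-style metabolomics study — log-normal
intensities, a paired or independent group design, batch structure with
monotone or smooth instrument drift over the injection sequence, pooled
QC samples injected at regular intervals, and optional missingness — plus
beta-uniform p-value draws, a toy schema-valid knowledge graph and random
substructure fingerprints.  Every generator is deterministic under its
seed and returns ground truth sufficient to compute recovery metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_data import BATCH_COL, Dataset, ORDER_COL, SUBJECT_COL, TYPE_COL
from .knowledge import KnowledgeGraph, build_graph
from .networks import FINGERPRINT_LENGTH, Fingerprint

__all__ = [
    "SimulationSpec",
    "simulate_intensity_dataset",
    "simulate_pvalues",
    "toy_knowledge_graph",
    "random_fingerprints",
]

DRIFT_AMPLITUDE = 0.3  # default 30% signal change across a batch


@dataclass
class SimulationSpec:
    """Study conditions for :func:`simulate_intensity_dataset`.

    ``n_samples`` counts biological samples per group (two groups).  With
    ``paired=True`` the two groups are repeated measures of the same
    subjects.  ``effect_d`` is the standardized mean shift (on the log
    scale) applied to the first ``n_effect`` features.  Drift multiplies
    intensities by a function of injection order with relative amplitude
    ``drift_amplitude``; QC (pooled) samples are inserted every
    ``qc_interval`` injections.
    """

    n_features: int = 100
    n_samples: int = 20
    paired: bool = True
    n_effect: int = 10
    effect_d: float = 2.0
    n_batches: int = 1
    drift: str = "none"  # none | linear | smooth
    drift_amplitude: float = DRIFT_AMPLITUDE
    qc_interval: int = 5
    missing_rate: float = 0.0
    base_log_mean: float = 10.0
    base_log_sd: float = 0.5
    noise_sd: float = 0.5
    seed: int = 0
    group_factor: str = "group"
    group_levels: tuple = ("control", "case")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_effect > self.n_features:
            raise ValueError("n_effect cannot exceed n_features")
        if self.drift not in ("none", "linear", "smooth"):
            raise ValueError(f"unknown drift model {self.drift!r}")


def simulate_intensity_dataset(spec: SimulationSpec) -> tuple[Dataset, pd.DataFrame]:
    """Simulate an intensity dataset plus its ground-truth table.

    Returns ``(dataset, truth)`` where ``truth`` is per-feature:
    ``has_effect`` (bool), ``effect_d`` and ``drifting`` (bool).
    Intensities are log-normal: feature baselines drawn once, subject
    effects shared within a pair, group effects added on the log2 scale.
    """
    rng = np.random.default_rng(spec.seed)
    n_bio = 2 * spec.n_samples
    feat_ids = [f"F{i + 1:04d}" for i in range(spec.n_features)]
    base = rng.normal(spec.base_log_mean, spec.base_log_sd, size=spec.n_features)

    # log2-scale signal for biological samples
    log_sig = np.tile(base[:, None], (1, n_bio)) + rng.normal(
        0, spec.noise_sd, size=(spec.n_features, n_bio)
    )
    group = np.array([0] * spec.n_samples + [1] * spec.n_samples)
    if spec.paired:
        subj_effect = rng.normal(0, spec.noise_sd, size=(spec.n_features, spec.n_samples))
        log_sig += np.concatenate([subj_effect, subj_effect], axis=1)
    effect = np.zeros(spec.n_features)
    effect[: spec.n_effect] = spec.effect_d * spec.noise_sd * (
        1 if not spec.paired else np.sqrt(2)
    )
    # paired analysis tests the within-subject difference whose sd is
    # sqrt(2)*noise_sd; scale so effect_d is the d of the analysed contrast
    log_sig += np.outer(effect, group)

    # QC signal: pooled sample, constant apart from noise
    bio_ids = [f"S{i + 1:03d}" for i in range(n_bio)]
    sample_rows = []
    columns = {}
    qc_count = 0
    order = 0
    per_batch = int(np.ceil(n_bio / spec.n_batches))
    qc_sd = spec.noise_sd / 4  # pooled material: much tighter than biology

    for b in range(spec.n_batches):
        batch_name = f"B{b + 1}"
        members = list(range(b * per_batch, min((b + 1) * per_batch, n_bio)))
        batch_positions = []

        def add_qc():
            nonlocal qc_count, order
            qc_count += 1
            order += 1
            sid = f"QC{qc_count:03d}"
            columns[sid] = base + rng.normal(0, qc_sd, size=spec.n_features)
            sample_rows.append(
                {"sample_id": sid, spec.group_factor: np.nan, SUBJECT_COL: np.nan,
                 BATCH_COL: batch_name, ORDER_COL: order, TYPE_COL: "qc"}
            )
            batch_positions.append((sid, order))

        add_qc()
        for j, idx in enumerate(members):
            order += 1
            sid = bio_ids[idx]
            columns[sid] = log_sig[:, idx]
            sample_rows.append(
                {
                    "sample_id": sid,
                    spec.group_factor: spec.group_levels[group[idx]],
                    SUBJECT_COL: f"subj{(idx % spec.n_samples) + 1:03d}"
                    if spec.paired
                    else f"subj{idx + 1:03d}",
                    BATCH_COL: batch_name,
                    ORDER_COL: order,
                    TYPE_COL: "biological",
                }
            )
            batch_positions.append((sid, order))
            if (j + 1) % spec.qc_interval == 0:
                add_qc()
        if batch_positions[-1][0].startswith("QC") is False:
            add_qc()

        # apply multiplicative drift within the batch
        if spec.drift != "none":
            orders = np.array([o for _, o in batch_positions], dtype=float)
            t = (orders - orders.min()) / max(orders.max() - orders.min(), 1)
            if spec.drift == "linear":
                curve = 1 - spec.drift_amplitude * t
            else:  # smooth: slow sinusoidal wander
                curve = 1 + spec.drift_amplitude / 2 * np.sin(2 * np.pi * t * 1.5)
            for (sid, _), c in zip(batch_positions, curve):
                columns[sid] = columns[sid] + np.log2(c)

    meta = pd.DataFrame(sample_rows).set_index("sample_id")
    mat = pd.DataFrame(
        {sid: np.power(2.0, columns[sid]) for sid in meta.index}, index=feat_ids
    )
    if spec.missing_rate > 0:
        mask = rng.random(mat.shape) < spec.missing_rate
        mat = mat.mask(mask)
    truth = pd.DataFrame(
        {
            "feature_id": feat_ids,
            "has_effect": [i < spec.n_effect for i in range(spec.n_features)],
            "effect_d": [spec.effect_d if i < spec.n_effect else 0.0
                         for i in range(spec.n_features)],
            "drifting": spec.drift != "none",
        }
    ).set_index("feature_id")
    return Dataset(mat, meta), truth


def simulate_pvalues(lam: float, a: float, n: int, seed: int) -> np.ndarray:
    """Draw p-values from the beta-uniform mixture λ·U(0,1) + (1-λ)·Beta(a, 1)."""
    if not 0 <= lam <= 1 or not 0 < a < 1:
        raise ValueError("need lambda in [0,1] and a in (0,1)")
    rng = np.random.default_rng(seed)
    from_uniform = rng.random(n) < lam
    p = np.where(from_uniform, rng.random(n), rng.random(n) ** (1 / a))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def toy_knowledge_graph() -> KnowledgeGraph:
    """A 12-node / 15-edge schema-valid toy graph.

    Contains a gene -> (CONVERSION) -> protein -> (CATALYSIS) -> compound
    path, a transcription-factor and a microRNA CONTROL regulator, and a
    pathway annotating three compounds (plus a gene and a protein).
    """
    nodes = pd.DataFrame(
        [
            ("G1", "gene", "gene G1"),
            ("G2", "gene", "gene G2"),
            ("G3", "gene", "gene G3"),
            ("P1", "protein", "enzyme P1"),
            ("P2", "protein", "enzyme P2"),
            ("TF1", "protein", "transcription factor TF1"),
            ("MIR1", "microRNA", "microRNA MIR1"),
            ("C1", "compound", "compound C1"),
            ("C2", "compound", "compound C2"),
            ("C3", "compound", "compound C3"),
            ("C4", "compound", "compound C4"),
            ("PW1", "pathway", "toy pathway"),
        ],
        columns=["id", "node_type", "name"],
    )
    edges = pd.DataFrame(
        [
            ("G1", "P1", "CONVERSION"),
            ("G2", "P2", "CONVERSION"),
            ("P1", "C1", "CATALYSIS"),
            ("P2", "C2", "CATALYSIS"),
            ("P1", "P2", "MOLECULAR_BINDING"),
            ("TF1", "G1", "CONTROL"),
            ("MIR1", "G2", "CONTROL"),
            ("C1", "C2", "BIOCHEMICAL_REACTION"),
            ("C3", "C4", "BIOCHEMICAL_REACTION"),
            ("G1", "G2", "GENETIC_ASSOCIATION"),
            ("PW1", "C1", "ANNOTATION"),
            ("PW1", "C2", "ANNOTATION"),
            ("PW1", "C3", "ANNOTATION"),
            ("PW1", "G1", "ANNOTATION"),
            ("PW1", "P1", "ANNOTATION"),
        ],
        columns=["source", "target", "relation_type"],
    )
    return build_graph(nodes, edges)


def random_fingerprints(
    n: int,
    length: int = FINGERPRINT_LENGTH,
    density: float = 0.1,
    seed: int = 0,
) -> list[Fingerprint]:
    """Independent Bernoulli(density) substructure fingerprints."""
    if not 0 < density < 1:
        raise ValueError("density must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    fps = []
    for i in range(n):
        bits = np.flatnonzero(rng.random(length) < density)
        fps.append(Fingerprint(f"CMP{i + 1:04d}", frozenset(int(b) for b in bits), length))
    return fps
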