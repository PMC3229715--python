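"""Synthetic Ct-value datasets with planted ground truth.

The generators emulate a TaqMan low-density-array study of PGRN-mutation
FTLD-TDP brain tissue: 664 miRNA assays on 40 patients (8 mutation
carriers vs 32 non-carriers), expression-dependent missingness that grows
with latent Ct, Ct > 35 censoring-prone wells, per-sample intensity
shifts, a minority of truly differential assays shifted by 0.5-2 Ct
cycles with signs split evenly, duplicate-well technical noise, and a
stable endogenous control (RNU48).  Every generator is bit-reproducible
given its seed, and returns the planted truth alongside the data so
downstream stages can be scored against it.

Sign convention throughout: lower Ct = higher expression, so an assay
"up" in the carrier group carries a *negative* planted Ct shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ct_io import CtMatrix, GroupDesign, MrnaDeTable, QpcrWellTable, TargetMap
from .errors import ConfigError


@dataclass
class ArraySimConfig:
    """Study-design parameters for the array simulator.

    Defaults mirror the profiled study: 664 assays, 8 vs 32 samples, a
    small minority of truly differential assays with effects of 0.5-2 Ct
    cycles, baseline Ct around 28 +/- 3, sample-level shifts of 0.5 Ct
    (removed by normalization), well noise of 0.6 Ct, and missingness
    that rises logistically with latent Ct around a midpoint of 34.
    """

    n_assays: int = 664
    n_group1: int = 8
    n_group2: int = 32
    n_true_de: int = 20
    effect_range_ct: tuple[float, float] = (0.5, 2.0)
    baseline_ct_mean: float = 28.0
    baseline_ct_sd: float = 3.0
    sample_shift_sd: float = 0.5
    noise_sd: float = 0.6
    missing_logistic_midpoint: float = 34.0
    missing_logistic_slope: float = 1.5
    censor_ct: float = 35.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_assays < 1 or self.n_group1 < 2 or self.n_group2 < 2:
            raise ConfigError("need n_assays >= 1 and at least 2 samples per group")
        if not 0 <= self.n_true_de <= self.n_assays:
            raise ConfigError("n_true_de must lie in [0, n_assays]")
        lo, hi = self.effect_range_ct
        if not (0 < lo <= hi):
            raise ConfigError("effect_range_ct must be positive with lo <= hi")
        if self.baseline_ct_sd <= 0 or self.missing_logistic_slope <= 0:
            raise ConfigError("scale parameters must be > 0")
        if self.sample_shift_sd < 0 or self.noise_sd < 0:
            raise ConfigError("noise parameters must be >= 0")


@dataclass
class SimTruth:
    """Planted ground truth attached to a simulated dataset."""

    de_assay_ids: set = field(default_factory=set)
    effect_ct: dict = field(default_factory=dict)  # assay_id -> signed Ct shift in group1
    planted_genes: dict = field(default_factory=dict)  # gene -> tuple of targeting miRNAs


def missingness_probability(
    latent_ct: np.ndarray, midpoint: float, slope: float
) -> np.ndarray:
    """Probability a well drops out, logistic in its latent Ct.

    ``p = 1 / (1 + exp(-(ct - midpoint) / slope))`` — low-abundance wells
    (high Ct) are the ones the instrument fails to call.
    """
    return 1.0 / (1.0 + np.exp(-(np.asarray(latent_ct) - midpoint) / slope))


def generate_array_dataset(
    config: ArraySimConfig,
) -> tuple[CtMatrix, GroupDesign, SimTruth]:
    """Simulate a raw Ct matrix plus sample sheet and planted truth.

    The latent cell value is baseline + group effect + sample shift +
    well noise; a cell is reported missing with the logistic dropout
    probability evaluated at its latent Ct.  Exactly ``n_true_de`` assays
    carry a group-1 shift drawn uniformly from ``effect_range_ct``, signs
    split as evenly as possible between up- and down-regulation.
    """
    rng = np.random.default_rng(config.seed)
    m, n1, n2 = config.n_assays, config.n_group1, config.n_group2
    n = n1 + n2

    assay_ids = [f"miR-sim-{i:04d}" for i in range(m)]
    sample_ids = [f"S{j:03d}" for j in range(n)]
    groups = ["PGRN+"] * n1 + ["PGRN-"] * n2
    # Carriers are uniformly pathology type 1; non-carriers span types 1-3.
    subtypes = ["type1"] * n1 + [f"type{1 + j % 3}" for j in range(n2)]
    design = GroupDesign(
        pd.DataFrame(
            {"group": groups, "tissue": "cortex", "subtype": subtypes},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    baseline = rng.normal(config.baseline_ct_mean, config.baseline_ct_sd, size=m)
    sample_shift = rng.normal(0.0, config.sample_shift_sd, size=n) if config.sample_shift_sd > 0 else np.zeros(n)

    de_idx = rng.choice(m, size=config.n_true_de, replace=False) if config.n_true_de else np.array([], dtype=int)
    lo, hi = config.effect_range_ct
    magnitudes = rng.uniform(lo, hi, size=config.n_true_de)
    # Half the effects negative (higher expression in group 1), half positive.
    signs = np.ones(config.n_true_de)
    signs[: config.n_true_de // 2] = -1.0
    rng.shuffle(signs)
    effects = np.zeros(m)
    effects[de_idx] = signs * magnitudes

    group1_mask = np.array([g == "PGRN+" for g in groups])
    latent = (
        baseline[:, None]
        + np.where(group1_mask[None, :], effects[:, None], 0.0)
        + sample_shift[None, :]
    )
    noise = rng.normal(0.0, config.noise_sd, size=(m, n)) if config.noise_sd > 0 else np.zeros((m, n))
    ct = latent + noise

    p_miss = missingness_probability(
        ct, config.missing_logistic_midpoint, config.missing_logistic_slope
    )
    missing = rng.random(size=(m, n)) < p_miss
    ct = np.where(missing, np.nan, ct)

    data = pd.DataFrame(ct, index=assay_ids, columns=sample_ids)
    truth = SimTruth(
        de_assay_ids={assay_ids[i] for i in de_idx},
        effect_ct={assay_ids[i]: float(effects[i]) for i in de_idx},
    )
    return CtMatrix(data, stage="raw"), design, truth


def generate_qpcr_plate(
    assay_ids: Sequence[str],
    design: GroupDesign,
    truth: SimTruth,
    dup_noise_sd: float = 0.15,
    outlier_rate: float = 0.02,
    baseline_ct_mean: float = 26.0,
    control_assay_id: str = "RNU48",
    seed: int = 0,
) -> QpcrWellTable:
    """Simulate a duplicate-well validation plate.

    Two wells per sample x assay; each pair shares a latent sample value
    and gets independent technical noise.  With probability
    ``outlier_rate`` one well of a pair is displaced by > 2 cycles to
    exercise the duplicate-reconciliation rule.  The endogenous control
    carries no group effect by construction.
    """
    if not assay_ids:
        raise ConfigError("assay_ids must be non-empty")
    if not 0 <= outlier_rate <= 1:
        raise ConfigError("outlier_rate must lie in [0, 1]")
    if dup_noise_sd < 0:
        raise ConfigError("dup_noise_sd must be >= 0")
    unknown = set(truth.effect_ct) - set(assay_ids)
    if unknown:
        raise ConfigError(f"truth refers to unknown assay id(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    all_assays = list(assay_ids)
    if control_assay_id not in all_assays:
        all_assays.append(control_assay_id)

    rows = []
    for assay in all_assays:
        base = baseline_ct_mean + rng.normal(0.0, 1.0)
        effect = 0.0 if assay == control_assay_id else truth.effect_ct.get(assay, 0.0)
        for sample in design.sample_ids:
            latent = base + (effect if design.group_of(sample) == "PGRN+" else 0.0)
            pair = latent + (
                rng.normal(0.0, dup_noise_sd, size=2) if dup_noise_sd > 0 else np.zeros(2)
            )
            if rng.random() < outlier_rate:
                which = int(rng.integers(2))
                # Displacement strictly beyond the 2-cycle reconciliation
                # threshold, always upward (a late-crossing well).
                pair[which] += 2.5 + rng.uniform(0.0, 2.0)
            rows.append((assay, sample, 1, float(pair[0])))
            rows.append((assay, sample, 2, float(pair[1])))
    wells = pd.DataFrame(rows, columns=["assay_id", "sample_id", "well_replicate", "ct"])
    return QpcrWellTable(wells, control_assay_id=control_assay_id)


def generate_integration_fixtures(
    n_decoy_genes: int,
    candidate_mirnas: Sequence[str],
    planted: SimTruth,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[TargetMap, MrnaDeTable, MrnaDeTable]:
    """Build target lists plus two tissue DE tables with planted truth.

    Planted genes (``planted.planted_genes``: gene -> tuple of targeting
    miRNAs) come out significantly down-regulated in both tissues and
    appear in their planted miRNAs' target lists.  Decoy genes are
    spoilers: down in only one tissue, up-regulated, non-significant, or
    down in both but predicted by no candidate miRNA — each decoy class
    fails exactly one filter of the anti-correlation selection.
    """
    for gene, mirnas in planted.planted_genes.items():
        if len(mirnas) > len(candidate_mirnas):
            raise ConfigError(
                f"gene {gene!r} planted with multiplicity {len(mirnas)} > "
                f"{len(candidate_mirnas)} candidate miRNAs"
            )
        unknown = set(mirnas) - set(candidate_mirnas)
        if unknown:
            raise ConfigError(f"gene {gene!r} planted on non-candidate miRNA(s): {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    targets: TargetMap = {m: set() for m in candidate_mirnas}
    for gene, mirnas in planted.planted_genes.items():
        for m in mirnas:
            targets[m].add(gene.upper())

    rows_a: list[tuple[str, str, str, float]] = []
    rows_b: list[tuple[str, str, str, float]] = []
    probeset = iter(range(10**6))

    def add(rows: list, gene: str, direction: str, p: float) -> None:
        rows.append((f"ps_{next(probeset):06d}", gene, direction, float(p)))

    sig = lambda: rng.uniform(1e-4, alpha * 0.9)  # noqa: E731 - clearly significant
    nonsig = lambda: rng.uniform(alpha * 1.2, 1.0)  # noqa: E731

    for gene in planted.planted_genes:
        add(rows_a, gene, "down", sig())
        add(rows_b, gene, "down", sig())

    decoy_kinds = ("one_tissue", "up_both", "nonsig", "untargeted_down")
    for i in range(n_decoy_genes):
        gene = f"DECOY{i:05d}"
        kind = decoy_kinds[i % len(decoy_kinds)]
        if kind == "one_tissue":
            add(rows_a, gene, "down", sig())
            add(rows_b, gene, "down", nonsig())
        elif kind == "up_both":
            add(rows_a, gene, "up", sig())
            add(rows_b, gene, "up", sig())
        elif kind == "nonsig":
            add(rows_a, gene, "down", nonsig())
            add(rows_b, gene, "down", nonsig())
        else:  # down in both but absent from every candidate target list
            add(rows_a, gene, "down", sig())
            add(rows_b, gene, "down", sig())
        if kind != "untargeted_down" and candidate_mirnas:
            # Decoys may still be predicted targets; the DE filters must
            # remove them regardless.
            m = candidate_mirnas[int(rng.integers(len(candidate_mirnas)))]
            targets[m].add(gene)

    cols = ["probeset_id", "gene_symbol", "direction", "p_value"]
    table_a = MrnaDeTable(pd.DataFrame(rows_a, columns=cols))
    table_b = MrnaDeTable(pd.DataFrame(rows_b, columns=cols))
    return targets, table_a, table_b
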