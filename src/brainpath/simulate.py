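"""Seeded synthetic cohorts with plantable edge-level connectivity disruption.

The generator emulates the kind of data the pipeline consumes: region-averaged
resting-state signals for a two-group cohort over a parcellation.  Each group
shares a true region correlation matrix built from a random low-rank-plus-
diagonal factor model (hence positive semi-definite by construction); subjects
are stationary Gaussian AR(1) processes in time with that spatial covariance.
Group differences are planted as *correlation attenuation* on chosen edges —
the patient group's true correlation on a planted edge is pulled toward zero
by ``effect_delta`` — mimicking disrupted functional connectivity.

A direct z-space generator (:func:`simulate_f_matrix`) plants a mean shift on
pathway-edge columns of an F matrix and is the calibration harness for the
subset search itself.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .catalog import ParcellationLabels
from .connectivity import PathwayConnectivityMatrix, RegionTimeSeries, write_time_series

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "generic_labels",
    "make_group_covariance",
    "simulate_cohort",
    "simulate_f_matrix",
    "write_cohort",
]

#: entries of the repaired matrix may move at most this far from the target
PSD_REPAIR_TOL = 0.02


@dataclass
class CohortSpec:
    """Parameters of a synthetic two-group cohort.

    Defaults mirror a realistic resting-state study: 116 regions, 94 retained
    volumes (100 acquired minus 6 discarded for signal equilibrium), and group
    sizes 22 vs 37 (the control-vs-early-impairment contrast; 61 is the
    late-stage group size for the other contrasts).  ``planted_edges`` are
    region-index pairs whose true correlation is ``planted_base_r`` in
    controls and attenuated toward zero by ``effect_delta`` in patients.
    ``ar_coefficient`` sets temporal smoothness of the AR(1) signals.
    """

    n_regions: int = 116
    n_timepoints: int = 94
    group_sizes: tuple[int, int] = (22, 37)
    n_factors: int = 10
    factor_noise: float = 5.0
    planted_edges: tuple[tuple[int, int], ...] = ()
    planted_base_r: float = 0.6
    effect_delta: float = 0.4
    ar_coefficient: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("AR coefficient must be in [0, 1)")
        if abs(self.planted_base_r) > 1:
            raise ValueError("planted base correlation must be in [-1, 1]")
        if abs(self.planted_base_r - np.sign(self.planted_base_r) * self.effect_delta) > 1:
            raise ValueError("effect delta pushes planted |r| beyond 1")
        seen = set()
        for a, b in self.planted_edges:
            if a == b or not (0 <= a < self.n_regions and 0 <= b < self.n_regions):
                raise ValueError(f"bad planted edge ({a}, {b})")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate planted edge ({a}, {b})")
            seen.add(key)


@dataclass
class GroundTruth:
    """True per-group correlation matrices and the planted disruption."""

    control_corr: np.ndarray
    patient_corr: np.ndarray
    planted_edges: tuple[tuple[int, int], ...]
    effect_delta: float
    seed: int


def _nearest_psd_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and renormalize to unit diagonal."""
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2)
    repaired = (vecs * np.maximum(vals, 1e-8)) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


def make_group_covariance(spec: CohortSpec, group: str = "control") -> np.ndarray:
    """True correlation matrix for one group (``"control"`` or ``"patient"``).

    The base matrix comes from a low-rank-plus-diagonal factor model shared by
    both groups.  Planted edges are set to ``planted_base_r`` in controls; in
    patients their magnitude is reduced by ``effect_delta`` (floored at zero).
    Edited matrices get a nearest-PSD repair, which preserves unplanted
    entries to within 0.02.
    """
    if group not in ("control", "patient"):
        raise ValueError("group must be 'control' or 'patient'")
    rng = np.random.default_rng(spec.seed)
    W = rng.normal(size=(spec.n_regions, spec.n_factors))
    sigma = W @ W.T + spec.factor_noise * np.eye(spec.n_regions)
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    if not spec.planted_edges:
        return corr
    base = spec.planted_base_r
    if group == "patient":
        target = np.sign(base) * max(abs(base) - spec.effect_delta, 0.0)
    else:
        target = base
    for a, b in spec.planted_edges:
        corr[a, b] = corr[b, a] = target
    return _nearest_psd_correlation(corr)


def generic_labels(n: int) -> ParcellationLabels:
    """Placeholder region names R001..Rn for non-atlas simulations."""
    width = max(3, len(str(n)))
    return ParcellationLabels(tuple(f"R{i + 1:0{width}d}" for i in range(n)))


def _ar1_series(
    rng: np.random.Generator, chol: np.ndarray, T: int, phi: float, burn: int = 50
) -> np.ndarray:
    """Stationary AR(1)-in-time series whose marginal spatial covariance is chol @ chol.T."""
    n = chol.shape[0]
    innov = rng.standard_normal((burn + T, n)) @ chol.T
    x = np.empty_like(innov)
    x[0] = innov[0]
    scale = np.sqrt(1.0 - phi**2)
    for t in range(1, burn + T):
        x[t] = phi * x[t - 1] + scale * innov[t]
    return x[burn:]


def simulate_cohort(
    spec: CohortSpec, labels: ParcellationLabels | None = None
) -> tuple[list[RegionTimeSeries], np.ndarray, GroundTruth]:
    """Draw a full two-group cohort of region time series from a spec.

    Returns subjects in group order (controls first, label 0; patients label
    1), the label vector, and the ground truth.  Reproducible from the seed.
    """
    if labels is None:
        labels = generic_labels(spec.n_regions)
    if len(labels) != spec.n_regions:
        raise ValueError("label count does not match n_regions")
    control_corr = make_group_covariance(spec, "control")
    patient_corr = make_group_covariance(spec, "patient")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    cohort: list[RegionTimeSeries] = []
    group_labels: list[int] = []
    for g, (size, corr) in enumerate(
        zip(spec.group_sizes, (control_corr, patient_corr))
    ):
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(spec.n_regions))
        for s in range(size):
            values = _ar1_series(rng, chol, spec.n_timepoints, spec.ar_coefficient)
            cohort.append(
                RegionTimeSeries(
                    subject_id=f"{'cn' if g == 0 else 'pt'}{s + 1:03d}",
                    values=values,
                    labels=labels,
                )
            )
            group_labels.append(g)
    truth = GroundTruth(
        control_corr=control_corr,
        patient_corr=patient_corr,
        planted_edges=spec.planted_edges,
        effect_delta=spec.effect_delta,
        seed=spec.seed,
    )
    return cohort, np.array(group_labels), truth


def simulate_f_matrix(
    n_per_group: tuple[int, int],
    n_edges: int,
    planted: Sequence[int] = (),
    delta: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    pathway_id: str = "synthetic",
) -> PathwayConnectivityMatrix:
    """Directly simulated pathway F matrix with a planted z-space mean shift.

    Edge columns are i.i.d. normal with standard deviation ``noise_sd``
    (exchangeable under the null); patient rows get ``delta`` added on the
    planted columns.  This isolates the subset search from the time-series
    stage for calibration studies.
    """
    n1, n2 = n_per_group
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, noise_sd, size=(n1 + n2, n_edges))
    planted = tuple(planted)
    if any(not 0 <= j < n_edges for j in planted):
        raise ValueError("planted column outside edge range")
    z[n1:, planted] += delta
    group_labels = np.array([0] * n1 + [1] * n2)
    return PathwayConnectivityMatrix(
        pathway_id=pathway_id,
        z=z,
        sample_ids=tuple(f"s{i:03d}" for i in range(n1 + n2)),
        group_labels=group_labels,
        edge_names=tuple(f"e{j}" for j in range(n_edges)),
    )


def write_cohort(
    cohort: Sequence[RegionTimeSeries],
    group_labels: Sequence[int],
    truth: GroundTruth,
    outdir: str | Path,
    spec: CohortSpec | None = None,
) -> Path:
    """Write per-subject TSVs, a cohort manifest, and a ground-truth sidecar.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = ["subject_id\tfile\tgroup"]
    for ts, g in zip(cohort, group_labels):
        fname = f"{ts.subject_id}.tsv"
        write_time_series(ts, outdir / fname)
        rows.append(f"{ts.subject_id}\t{fname}\t{g}")
    manifest = outdir / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    sidecar = {
        "planted_edges": [list(e) for e in truth.planted_edges],
        "effect_delta": truth.effect_delta,
        "seed": truth.seed,
    }
    if spec is not None:
        spec_dict = asdict(spec)
        spec_dict["planted_edges"] = [list(e) for e in spec.planted_edges]
        sidecar["spec"] = spec_dict
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar, indent=2))
    return manifest
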