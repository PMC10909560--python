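"""Synthetic indicator panels with known latent group structure.

Real inputs to this kind of classification are census aggregates that are
large, slow to obtain and awkward to redistribute.  Everything downstream is
therefore exercised on simulated panels: each area belongs to one of G latent
groups; each group follows its own polynomial mean trajectory per indicator;
observed values are the group mean at the coded time plus Gaussian noise,
clipped to the percentage scale.  The generator also knows the availability
pattern of the census design — two indicators observed at all four censuses,
the four age/tenure indicators absent at the first — so that missing-data
handling is tested under the conditions the method actually faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import INDICATORS, IndicatorPanel


def default_availability(n_indicators: int = 6, n_timepoints: int = 4) -> np.ndarray:
    """Census availability pattern: indicators 2+ unobserved at the first time.

    The two in-mover share indicators exist at every census; the four
    age-band and tenure indicators only from the second census onwards.
    """
    avail = np.ones((n_indicators, n_timepoints), dtype=bool)
    avail[2:, 0] = False
    return avail


@dataclass
class SimulationSpec:
    """True data-generating process for a synthetic panel.

    ``traj_coeffs[g, k, p]`` is the coefficient on ``t**p`` of group ``g``'s
    mean trajectory for indicator ``k``, on the percentage scale with time
    coded 0..T-1.  ``noise_sd`` is either one SD per indicator (shape ``(K,)``)
    or one per group and indicator (shape ``(G, K)``), in percentage points.
    """

    n_areas: int
    group_props: np.ndarray
    traj_coeffs: np.ndarray
    noise_sd: np.ndarray
    n_timepoints: int = 4
    availability: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.group_props = np.asarray(self.group_props, dtype=float)
        self.traj_coeffs = np.asarray(self.traj_coeffs, dtype=float)
        self.noise_sd = np.asarray(self.noise_sd, dtype=float)
        if self.n_areas < 1:
            raise ValueError("n_areas must be positive")
        if self.n_timepoints < 1:
            raise ValueError("n_timepoints must be positive")
        if self.traj_coeffs.ndim != 3:
            raise ValueError("traj_coeffs must have shape (G, K, order+1)")
        g, k, p = self.traj_coeffs.shape
        if not np.isfinite(self.traj_coeffs).all():
            raise ValueError("traj_coeffs must be finite")
        if self.group_props.shape != (g,):
            raise ValueError("group_props length must match traj_coeffs groups")
        if abs(self.group_props.sum() - 1.0) > 1e-12 or (self.group_props < 0).any():
            raise ValueError("group_props must be nonnegative and sum to 1")
        if self.noise_sd.shape not in ((k,), (g, k)):
            raise ValueError("noise_sd must have shape (K,) or (G, K)")
        if not (self.noise_sd > 0).all():
            raise ValueError("all noise_sd must be > 0")
        if self.availability is None:
            self.availability = (
                default_availability(k, self.n_timepoints)
                if (k, self.n_timepoints) == (6, 4)
                else np.ones((k, self.n_timepoints), dtype=bool)
            )
        self.availability = np.asarray(self.availability, dtype=bool)
        if self.availability.shape != (k, self.n_timepoints):
            raise ValueError("availability must have shape (K, T)")
        if not self.availability.any(axis=1).all():
            raise ValueError("every indicator needs at least one available time point")

    @property
    def n_groups(self) -> int:
        return self.traj_coeffs.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.traj_coeffs.shape[1]

    def group_means(self) -> np.ndarray:
        """Trajectory means, shape (G, K, T), evaluated at coded times."""
        t = np.arange(self.n_timepoints, dtype=float)
        powers = t[None, :] ** np.arange(self.traj_coeffs.shape[2])[:, None]  # (P, T)
        return np.einsum("gkp,pt->gkt", self.traj_coeffs, powers)


@dataclass
class SimulatedPanel:
    """A generated panel together with its ground-truth group labels (1..G)."""

    panel: IndicatorPanel
    true_labels: np.ndarray
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        if len(self.true_labels) != self.panel.n_areas:
            raise ValueError("one label per area required")
        if self.true_labels.min() < 1:
            raise ValueError("labels are 1-based group indices")


def generate_panel(spec: SimulationSpec) -> SimulatedPanel:
    """Draw a panel from the latent-group trajectory process.

    Group membership is sampled from ``group_props``; each observed cell is
    the group's polynomial mean plus Gaussian noise, clipped to [0, 100].
    Cells the availability pattern marks unobservable are missing.  A single
    seed drives group draws then noise, area-major, so identical specs give
    bitwise-identical panels.
    """
    rng = np.random.default_rng(spec.seed)
    n, k, t = spec.n_areas, spec.n_indicators, spec.n_timepoints
    labels0 = rng.choice(spec.n_groups, size=n, p=spec.group_props)
    means = spec.group_means()[labels0]  # (N, K, T)
    if spec.noise_sd.ndim == 1:
        sd = spec.noise_sd[None, :, None]
    else:
        sd = spec.noise_sd[labels0][:, :, None]
    raw = means + rng.standard_normal((n, k, t)) * sd
    clipped = np.clip(raw, 0.0, 100.0)
    n_clipped = int((raw != clipped).sum())
    mask = np.broadcast_to(spec.availability[None], (n, k, t)).copy()
    names = INDICATORS if k == 6 else tuple(f"indicator_{j + 1}" for j in range(k))
    years = 1981 + 10 * np.arange(t) if t == 4 else 2001 + np.arange(t)
    panel = IndicatorPanel(
        values=np.where(mask, clipped, np.nan),
        mask=mask,
        area_ids=np.array([f"W{i:05d}" for i in range(n)]),
        years=years,
        indicators=names,
    )
    return SimulatedPanel(panel=panel, true_labels=labels0 + 1, n_clipped=n_clipped)


def three_group_spec(n_areas: int = 2000, seed: int = 0, noise_sd: float = 2.0) -> SimulationSpec:
    """Reference three-group study design used by the recovery experiments.

    Mixing proportions (0.2, 0.3, 0.5); linear trajectories whose
    between-group gaps are at least 10 percentage points everywhere on the
    coded time range — five noise SDs at the default 2 pp noise — under the
    census availability pattern.  Means stay inside [0, 100] so clipping is
    inactive.
    """
    coeffs = np.array(
        [
            # [intercept, slope] per indicator, group 1
            [[10, 2], [5, 1], [20, 3], [15, 0], [10, 1], [20, 0]],
            # group 2
            [[35, 0], [25, 1], [45, 0], [40, 1], [35, -1], [45, 2]],
            # group 3
            [[60, -2], [50, 0], [70, -1], [70, 0], [65, 1], [75, -1]],
        ],
        dtype=float,
    )
    return SimulationSpec(
        n_areas=n_areas,
        group_props=np.array([0.2, 0.3, 0.5]),
        traj_coeffs=coeffs,
        noise_sd=np.full(6, noise_sd),
        n_timepoints=4,
        availability=default_availability(),
        seed=seed,
    )


def generate_area_lookup(
    n_source: int, n_target: int, seed: int = 0, weighted: bool = True
):
    """Random source-to-target boundary lookup for interpolation tests.

    Every source maps to between one and three targets.  With
    ``weighted=True`` the rows carry proportions summing to one per source;
    otherwise the weight column is absent, exercising the equal-split path.
    """
    from .interpolation import AreaLookup

    if n_source < 1 or n_target < 1:
        raise ValueError("n_source and n_target must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_source):
        k = int(rng.integers(1, min(3, n_target) + 1))
        targets = rng.choice(n_target, size=k, replace=False)
        if weighted:
            w = rng.dirichlet(np.ones(k))
            w = w / w.sum()
            for tgt, wt in zip(targets, w):
                rows.append((f"S{s:05d}", f"T{tgt:05d}", wt))
        else:
            for tgt in targets:
                rows.append((f"S{s:05d}", f"T{tgt:05d}", np.nan))
    df = pd.DataFrame(rows, columns=["source_id", "target_id", "weight"])
    if not weighted:
        df = df.drop(columns=["weight"])
    return AreaLookup(df)


def generate_paired_classifications(
    n_areas: int, r: int, c: int, association: float, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Two categorical labelings with tunable association.

    ``association=0`` gives independent uniform labels; ``association=1``
    makes the second labelling a deterministic surjection of the first
    (identity when ``r == c``, so Cramér's V is exactly 1).  Intermediate
    values mix the two regimes cell-wise.
    """
    if r < 2 or c < 2:
        raise ValueError("r and c must be >= 2")
    if not 0.0 <= association <= 1.0:
        raise ValueError("association must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    a = rng.integers(1, r + 1, size=n_areas)
    mapped = ((a - 1) % c) + 1
    independent = rng.integers(1, c + 1, size=n_areas)
    follow = rng.random(n_areas) < association
    b = np.where(follow, mapped, independent)
    return a, b
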