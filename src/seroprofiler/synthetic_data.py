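"""Synthetic case-control autoantibody cohorts with a planted-truth ledger.

The generator emulates the statistical structure of a serum reactivity
screen on a folded-protein array: ~1,631 non-control proteins printed in
quadruplicate per slide, two positive-control species, and a 20 vs 20
case-control cohort.  The signal model is multiplicative log-normal
throughout, which keeps intensities non-negative and reproduces the heavy
right tail typical of scanner RFU:

    T[p, s] = B_p * A_s * E[p, s]

with a per-protein baseline ``B_p ~ LogNormal(ln 500, 0.8)``, a per-sample
scale factor ``A_s ~ LogNormal(0, 0.2)`` (what quantile normalization must
remove), and a planted enrichment ``E`` equal to ``effect`` for marker
proteins in a randomly chosen penetrance-fraction of the enriched group's
samples (cases for "up" markers, controls for "down" markers — mirroring
autoantibodies respectively raised and depressed in patients), else 1.
Replicate foregrounds add log-normal spot noise with sigma chosen so the
replicate CV matches ``replicate_cv``; backgrounds are log-normal around
``bg_mean``.  The defining feature being exercised is *penetrance*: only a
subset of the enriched group reacts, which is exactly what the
penetrance fold-change statistic is designed to detect.

Randomness derives from a single root seed through per-protein substreams
(``SeedSequence(seed, spawn_key=(protein_index,))``), so changing the
protein count never reshuffles other proteins' draws, and the same seed
yields byte-identical output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import SampleManifest

# spawn-key namespaces for the substreams
_PROTEIN_NS = 0
_SAMPLE_NS = 1
_DESIGN_NS = 2
_CONTROL_NS = 3


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort and signal-model parameters (intensities in RFU)."""

    n_case: int = 20
    n_control: int = 20
    n_proteins: int = 1631
    n_replicates: int = 4
    n_up: int = 0
    n_down: int = 0
    effect: float = 4.0
    penetrance: float = 0.5
    baseline_log_mean: float = math.log(500.0)
    baseline_log_sd: float = 0.8
    sample_scale_sd: float = 0.2
    replicate_cv: float = 0.08
    bg_mean: float = 80.0
    bg_log_sd: float = 0.3
    control_levels: dict = field(
        default_factory=lambda: {"IgG": 40000.0, "Cy3BSA": 25000.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_proteins:
            raise ValueError("more planted markers than proteins")
        if not 0 < self.penetrance <= 1:
            raise ValueError("penetrance must be in (0, 1]")
        if not self.effect > 1:
            raise ValueError("effect must be > 1")
        if min(self.n_case, self.n_control, self.n_proteins, self.n_replicates) < 1:
            raise ValueError("cohort dimensions must be positive")


@dataclass
class SyntheticTruth:
    """Planted-marker ledger: direction, effect, penetrance, affected samples."""

    markers: dict[str, dict]

    def ids(self, direction: str | None = None) -> list[str]:
        return [
            p
            for p, m in self.markers.items()
            if direction is None or m["direction"] == direction
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "protein_id": p,
                "direction": m["direction"],
                "effect": m["effect"],
                "penetrance": m["penetrance"],
                "affected_samples": ";".join(m["affected_samples"]),
            }
            for p, m in sorted(self.markers.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["protein_id", "direction", "effect", "penetrance", "affected_samples"],
        )


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _replicate_sigma(cv: float) -> float:
    # log-normal CV = sqrt(exp(sigma^2) - 1)
    return math.sqrt(math.log1p(cv * cv))


def generate_cohort(
    config: SyntheticConfig | None = None,
) -> tuple[pd.DataFrame, SampleManifest, SyntheticTruth]:
    """Generate a spot table, manifest and truth ledger.

    The spot table has one row per printed spot (protein x slide x
    replicate, plus quadruplicate control spots per slide) in the standard
    seven-column schema; identical configs produce identical tables.
    """
    cfg = config or SyntheticConfig()
    n_samples = cfg.n_case + cfg.n_control
    case_ids = [f"CASE{i + 1:02d}" for i in range(cfg.n_case)]
    ctrl_ids = [f"CTRL{i + 1:02d}" for i in range(cfg.n_control)]
    sample_ids = case_ids + ctrl_ids
    manifest = SampleManifest(
        sample_ids=sample_ids,
        groups={**{s: "case" for s in case_ids}, **{s: "control" for s in ctrl_ids}},
    )
    proteins = [f"PROT{i + 1:05d}" for i in range(cfg.n_proteins)]

    # per-sample scale factors, one substream per sample index
    scales = np.array(
        [
            _rng(cfg.seed, _SAMPLE_NS, j).lognormal(0.0, cfg.sample_scale_sd)
            for j in range(n_samples)
        ]
    )

    # planted design: which proteins carry markers, and which samples react
    design_rng = _rng(cfg.seed, _DESIGN_NS)
    planted = design_rng.choice(cfg.n_proteins, size=cfg.n_up + cfg.n_down, replace=False)
    up_idx = set(int(i) for i in planted[: cfg.n_up])
    down_idx = set(int(i) for i in planted[cfg.n_up :])
    markers: dict[str, dict] = {}

    sigma_r = _replicate_sigma(cfg.replicate_cv)
    frames: list[pd.DataFrame] = []
    fg_rows = np.empty((cfg.n_proteins, n_samples, cfg.n_replicates))
    bg_rows = np.empty_like(fg_rows)

    for i in range(cfg.n_proteins):
        rng = _rng(cfg.seed, _PROTEIN_NS, i)
        baseline = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd)
        enrichment = np.ones(n_samples)
        if i in up_idx or i in down_idx:
            direction = "up" if i in up_idx else "down"
            group = case_ids if direction == "up" else ctrl_ids
            offset = 0 if direction == "up" else cfg.n_case
            n_affected = max(1, int(round(cfg.penetrance * len(group))))
            affected = sorted(rng.choice(len(group), size=n_affected, replace=False))
            enrichment[[offset + a for a in affected]] = cfg.effect
            markers[proteins[i]] = {
                "direction": direction,
                "effect": cfg.effect,
                "penetrance": cfg.penetrance,
                "affected_samples": [group[a] for a in affected],
            }
        true_signal = baseline * scales * enrichment
        rep_noise = rng.lognormal(0.0, sigma_r, size=(n_samples, cfg.n_replicates))
        fg_rows[i] = true_signal[:, None] * rep_noise
        bg_rows[i] = rng.lognormal(
            math.log(cfg.bg_mean), cfg.bg_log_sd, size=(n_samples, cfg.n_replicates)
        )

    rep_idx = np.arange(1, cfg.n_replicates + 1)
    frames.append(
        pd.DataFrame(
            {
                "slide_id": np.repeat(np.tile(sample_ids, cfg.n_proteins), cfg.n_replicates),
                "protein_id": np.repeat(proteins, n_samples * cfg.n_replicates),
                "replicate_index": np.tile(rep_idx, cfg.n_proteins * n_samples),
                "fg_median": fg_rows.reshape(-1),
                "bg_median": bg_rows.reshape(-1),
                "is_control": False,
                "control_kind": "none",
            }
        )
    )

    # positive-control spots, quadruplicate per slide
    for k, (kind, level) in enumerate(sorted(cfg.control_levels.items())):
        rng = _rng(cfg.seed, _CONTROL_NS, k)
        noise = rng.lognormal(0.0, sigma_r, size=(n_samples, cfg.n_replicates))
        bg = rng.lognormal(
            math.log(cfg.bg_mean), cfg.bg_log_sd, size=(n_samples, cfg.n_replicates)
        )
        frames.append(
            pd.DataFrame(
                {
                    "slide_id": np.repeat(sample_ids, cfg.n_replicates),
                    "protein_id": f"CTRL_{kind}",
                    "replicate_index": np.tile(rep_idx, n_samples),
                    "fg_median": (level * noise).reshape(-1),
                    "bg_median": bg.reshape(-1),
                    "is_control": True,
                    "control_kind": kind,
                }
            )
        )

    spots = pd.concat(frames, ignore_index=True)
    return spots, manifest, SyntheticTruth(markers=markers)


def expected_truth_recovery(
    truth: SyntheticTruth, records: list
) -> dict[str, float]:
    """Score classified records against the planted truth.

    Sensitivity is the fraction of planted markers recovered with the
    correct direction ("up" -> increased, "down" -> decreased); false
    discoveries are null proteins classified either direction.
    """
    by_id = {r.protein_id: r.classification for r in records}
    missing = [p for p in truth.markers if p not in by_id]
    if missing:
        raise ValueError(f"truth proteins absent from records: {missing[:5]}")
    want = {"up": "increased", "down": "decreased"}
    planted = truth.markers
    hits = sum(
        1 for p, m in planted.items() if by_id[p] == want[m["direction"]]
    )
    hits_up = sum(
        1
        for p, m in planted.items()
        if m["direction"] == "up" and by_id[p] == "increased"
    )
    hits_down = sum(
        1
        for p, m in planted.items()
        if m["direction"] == "down" and by_id[p] == "decreased"
    )
    n_up = len(truth.ids("up"))
    n_down = len(truth.ids("down"))
    null_ids = [p for p in by_id if p not in planted]
    false_disc = sum(1 for p in null_ids if by_id[p] != "not_significant")
    return {
        "sensitivity": hits / len(planted) if planted else float("nan"),
        "sensitivity_up": hits_up / n_up if n_up else float("nan"),
        "sensitivity_down": hits_down / n_down if n_down else float("nan"),
        "false_discovery_count": float(false_disc),
        "false_discovery_fraction": false_disc / len(null_ids) if null_ids else 0.0,
        "n_null": float(len(null_ids)),
    }
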