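"""Factorial optimisation experiment over acquisition, reconstruction and
analysis parameters.

A *design* is one combination of administered activity, collimator, OSEM
update count, Butterworth cutoff (or none) and CV kernel size, evaluated
on either the whole or the reduced lung.  For every design, 40 (or a
configured number of) noise realisations of the healthy and diseased
phantoms are reconstructed, filtered and scored with AUC(CV_T); the two
score groups are compared with the Mann-Whitney U test and designs are
ranked by ascending p value.

The dominant cost, reconstruction, is shared: one OSEM pass per
(collimator, activity, realisation) produces snapshots at every update
count in the grid, and every (cutoff, kernel, lung-volume) design reuses
them.
"""

from __future__ import annotations

import itertools
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cvt
from .config import ExperimentConfig
from .errors import CvtSpectError
from .noise import NoiseConfig, make_realizations, target_counts
from .phantom import apply_motion_blur, build_activity, build_attenuation, build_lung_mask, place_lesions
from .postfilter import FilterSpec, apply_filter
from .projector import SystemModel, forward_project
from .recon import OsemReconstructor, ReconConfig
from .segmentation import erode_mask, segment_lung
from .stats import DesignResult, TestResult, mann_whitney, rank_designs

log = logging.getLogger("cvtspect")


@dataclass(frozen=True)
class Design:
    collimator: str
    activity_mbq: int
    n_iterations: int
    cutoff_cm: float | None
    kernel_cm: float
    lung_volume: str = "whole"

    def n_updates(self, n_subsets: int = 16) -> int:
        return self.n_iterations * n_subsets

    @property
    def design_id(self) -> str:
        q = "none" if self.cutoff_cm is None else f"{self.cutoff_cm:g}"
        return (f"{self.collimator}-{self.activity_mbq}MBq-it{self.n_iterations}"
                f"-q{q}-k{self.kernel_cm:g}-{self.lung_volume}")


@dataclass(frozen=True)
class DesignGrid:
    """Factorial axes; the clinical study grid is the default."""

    activities: tuple[int, ...] = (25, 125)
    collimators: tuple[str, ...] = ("LEHR", "LEGP")
    iteration_counts: tuple[int, ...] = tuple(range(2, 21, 2))
    cutoffs: tuple[float | None, ...] = (0.4, 0.5, 0.6, 0.7, None)
    kernels_cm: tuple[float, ...] = (1.0, 1.7, 2.3, 3.0)
    lung_volumes: tuple[str, ...] = ("whole", "reduced")

    @property
    def n_designs_per_volume(self) -> int:
        return (len(self.activities) * len(self.collimators) * len(self.iteration_counts)
                * len(self.cutoffs) * len(self.kernels_cm))

    def designs(self, lung_volume: str | None = None) -> list[Design]:
        volumes = self.lung_volumes if lung_volume is None else (lung_volume,)
        return [
            Design(col, act, it, q, k, lv)
            for col, act, it, q, k, lv in itertools.product(
                self.collimators, self.activities, self.iteration_counts,
                self.cutoffs, self.kernels_cm, volumes)
        ]


def enumerate_designs(grid: DesignGrid, lung_volume: str | None = None) -> list[Design]:
    return grid.designs(lung_volume)


class Experiment:
    """Caches phantoms, system models and noiseless projections across designs."""

    def __init__(self, config: ExperimentConfig):
        self.config = config
        self._phantom = None
        self._systems: dict[str, SystemModel] = {}
        self._noiseless: dict[tuple[str, bool], object] = {}

    # -- shared artifacts --------------------------------------------------

    def phantom(self):
        if self._phantom is None:
            spec = self.config.phantom
            t0 = time.perf_counter()
            mask = build_lung_mask(spec)
            lesions = place_lesions(mask, spec, seed=spec.seed)
            act_h = apply_motion_blur(build_activity(mask, None, spec), spec)
            act_c = apply_motion_blur(build_activity(mask, lesions, spec), spec)
            mu = build_attenuation(spec, mask)
            log.info("phantom built in %.1fs (lung %.3f l, lesion fraction %.4f)",
                     time.perf_counter() - t0, mask.volume_litres,
                     lesions.sum() / mask.values.sum())
            self._phantom = {"mask": mask, "lesions": lesions, "healthy": act_h,
                             "copd": act_c, "mu": mu}
        return self._phantom

    def system(self, collimator: str) -> SystemModel:
        if collimator not in self._systems:
            t0 = time.perf_counter()
            self._systems[collimator] = SystemModel(
                self.phantom()["mu"], self.config.geometry, collimator,
                n_distance_bins=self.config.n_distance_bins,
            )
            log.info("system model (%s) built in %.1fs", collimator, time.perf_counter() - t0)
        return self._systems[collimator]

    def noiseless_projections(self, collimator: str, diseased: bool):
        key = (collimator, diseased)
        if key not in self._noiseless:
            ph = self.phantom()
            t0 = time.perf_counter()
            self._noiseless[key] = forward_project(
                ph["copd" if diseased else "healthy"], ph["mu"],
                self.config.geometry, collimator, system=self.system(collimator),
            )
            log.info("noiseless projections (%s, %s) in %.1fs", collimator,
                     "copd" if diseased else "healthy", time.perf_counter() - t0)
        return self._noiseless[key]

    def realisations(self, collimator: str, activity_mbq: int, diseased: bool):
        noiseless = self.noiseless_projections(collimator, diseased)
        total = target_counts(collimator, activity_mbq) * self.config.count_scale()
        cfg = NoiseConfig(target_total_counts=total,
                          n_realisations=self.config.n_realisations,
                          base_seed=self.config.base_seed)
        stream = f"{collimator}-{activity_mbq}-{'copd' if diseased else 'healthy'}"
        return make_realizations(noiseless, cfg, stream=stream)

    def reconstruction_stacks(self, collimator: str, activity_mbq: int,
                              iteration_counts: tuple[int, ...]):
        """{diseased: {n_iter: [image per realisation]}} as float32 arrays."""
        its = tuple(sorted(set(iteration_counts)))
        recon = OsemReconstructor(
            self.phantom()["mu"], self.config.geometry, collimator,
            ReconConfig(n_subsets=self.config.n_subsets, n_iterations=max(its)),
            system=self.system(collimator),
        )
        stacks = {}
        for diseased in (False, True):
            t0 = time.perf_counter()
            per_iter = {it: [] for it in its}
            for noisy in self.realisations(collimator, activity_mbq, diseased):
                snaps = recon.reconstruct(noisy, snapshots_at=its)
                for it in its:
                    img = snaps[it]
                    img.values = img.values.astype(np.float32)
                    per_iter[it].append(img)
            stacks[diseased] = per_iter
            log.info("reconstructed %d x %d images (%s, %d MBq, %s) in %.1fs",
                     self.config.n_realisations, len(its), collimator, activity_mbq,
                     "copd" if diseased else "healthy", time.perf_counter() - t0)
        return stacks

    # -- evaluation --------------------------------------------------------

    def evaluate(self, designs: list[Design]) -> list[DesignResult]:
        """Run every design, sharing reconstructions; failures are recorded
        per design and the grid continues."""
        results: list[DesignResult] = []
        keyfn = lambda d: (d.collimator, d.activity_mbq)
        for (collimator, activity), group in itertools.groupby(sorted(designs, key=keyfn), keyfn):
            group = list(group)
            its = tuple(sorted({d.n_iterations for d in group}))
            try:
                stacks = self.reconstruction_stacks(collimator, activity, its)
            except CvtSpectError as exc:
                results += [self._failed(d, "reconstruction", exc) for d in group]
                continue
            for (it, cutoff), sub in itertools.groupby(
                    sorted(group, key=lambda d: (d.n_iterations, _qkey(d.cutoff_cm))),
                    lambda d: (d.n_iterations, d.cutoff_cm)):
                sub = list(sub)
                try:
                    results += self._evaluate_cell(sub, stacks, it, cutoff)
                except CvtSpectError as exc:
                    results += [self._failed(d, "filter/segment", exc) for d in sub]
        return results

    def _evaluate_cell(self, designs, stacks, n_iter, cutoff) -> list[DesignResult]:
        spec = FilterSpec(cutoff_cm=cutoff)
        filtered = {
            diseased: [apply_filter(img, spec) for img in stacks[diseased][n_iter]]
            for diseased in (False, True)
        }
        mean_healthy = filtered[False][0].copy_with(
            np.mean([im.values for im in filtered[False]], axis=0))
        whole = segment_lung(mean_healthy)
        masks = {"whole": whole, "reduced": erode_mask(whole)}

        out = []
        for d in designs:
            try:
                out.append(self._score_design(d, filtered, masks[d.lung_volume]))
            except CvtSpectError as exc:
                out.append(self._failed(d, "cv-analysis", exc))
        return out

    def _score_design(self, d: Design, filtered, mask) -> DesignResult:
        kernel = cvt.KernelConfig(d.kernel_cm, self.config.phantom.voxel_size_cm)
        cvs = {
            diseased: [cvt.kernel_cv_values(img, mask, kernel) for img in filtered[diseased]]
            for diseased in (False, True)
        }
        mean_curve = cvt.mean_frequency_function([cvt.density_curve(v) for v in cvs[False]])
        cv_t = cvt.modal_cv(mean_curve)
        auc_h = np.array([cvt.auc_above(v, cv_t) for v in cvs[False]])
        auc_c = np.array([cvt.auc_above(v, cv_t) for v in cvs[True]])
        test = mann_whitney(auc_c, auc_h)
        return DesignResult(
            design_id=d.design_id, collimator=d.collimator, activity_mbq=d.activity_mbq,
            n_iterations=d.n_iterations, n_updates=d.n_updates(self.config.n_subsets),
            cutoff_cm=d.cutoff_cm, kernel_cm=d.kernel_cm, lung_volume=d.lung_volume,
            cv_t=cv_t, test=test, auc_healthy=auc_h, auc_copd=auc_c,
        )

    def _failed(self, d: Design, stage: str, exc: Exception) -> DesignResult:
        log.warning("design %s failed at %s: %s", d.design_id, stage, exc)
        return DesignResult(
            design_id=d.design_id, collimator=d.collimator, activity_mbq=d.activity_mbq,
            n_iterations=d.n_iterations, n_updates=d.n_updates(self.config.n_subsets),
            cutoff_cm=d.cutoff_cm, kernel_cm=d.kernel_cm, lung_volume=d.lung_volume,
            cv_t=float("nan"),
            test=TestResult(float("nan"), float("nan"), float("nan"), 0, 0),
            failed=True, failure=f"{stage}: {exc}",
        )


def _qkey(cutoff):
    return -1.0 if cutoff is None else float(cutoff)


def run_design(design: Design, experiment: Experiment) -> DesignResult:
    """Evaluate a single design through the shared experiment caches."""
    return experiment.evaluate([design])[0]


def report(results: list[DesignResult], family_size: int | None = None) -> pd.DataFrame:
    """Tabulate all designs with ranks; columns follow the optimisation
    table layout (rank, kernel, iterations (updates), cutoff, p)."""
    if not any(not r.failed for r in results):
        raise CvtSpectError("no successful design to report")
    m = family_size if family_size is not None else sum(not r.failed for r in results)
    rank_designs(results)
    rows = [{
        "rank": np.nan if r.rank is None else float(r.rank),
        "design_id": r.design_id,
        "collimator": r.collimator,
        "activity_mbq": r.activity_mbq,
        "kernel_cm": r.kernel_cm,
        "n_iterations": r.n_iterations,
        "n_updates": r.n_updates,
        "cutoff_cm": np.nan if r.cutoff_cm is None else r.cutoff_cm,
        "lung_volume": r.lung_volume,
        "cv_t_percent": r.cv_t,
        "z": r.test.z_statistic,
        "p_value": r.test.p_value,
        "significant_bonferroni": (not r.failed) and r.test.significant_after_bonferroni(m),
        "failed": r.failed,
        "failure": r.failure,
    } for r in results]
    df = pd.DataFrame(rows).sort_values(
        ["failed", "rank"], na_position="last").reset_index(drop=True)
    return df


def top_table(df: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    cols = ["rank", "kernel_cm", "n_iterations", "n_updates", "cutoff_cm", "p_value"]
    return df[df["rank"].notna()].nsmallest(k, "rank")[cols].reset_index(drop=True)
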