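"""Batch processing of section images through a local work queue.

Every recognized raster file under a directory tree becomes one job holding
the full parameter set of the analysis. Jobs run independently
(segmentation followed by descriptor extraction); a failing job records its
error without stopping the queue, and the result table is sorted by image
path so it is identical regardless of worker count.
"""

from __future__ import annotations

import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from lungmorph.descriptors import compute_descriptors
from lungmorph.segmentation import SegmentationParams, segment_section

__all__ = ["JobDescription", "collect_jobs", "run_queue", "RESULT_COLUMNS"]

RASTER_EXTENSIONS = (".tif", ".tiff", ".png")

RESULT_COLUMNS = [
    "job_id",
    "image",
    "status",
    "error",
    "n_airspaces",
    "n_intercepts",
    "Lm_um",
    "D0_um",
    "D1_um",
    "D2_um",
]


@dataclass
class JobDescription:
    """One image to process, with all analysis parameters attached."""

    image_path: Path
    output_path: Path | None
    params: SegmentationParams
    job_id: int
    status: str = "pending"  # pending | running | done | failed
    error: str | None = None


def collect_jobs(
    root_dir: str | Path,
    params: SegmentationParams | None = None,
    output_dir: str | Path | None = None,
) -> list[JobDescription]:
    """Walk a directory tree and create one job per raster file.

    Files are ordered lexicographically by path for determinism. Files that
    are not readable are enqueued with status "failed" so the rest of the
    batch is unaffected.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise FileNotFoundError(f"not a directory: {root}")
    params = params or SegmentationParams()
    out = Path(output_dir) if output_dir is not None else None
    paths = sorted(
        p for p in root.rglob("*") if p.is_file() and p.suffix.lower() in RASTER_EXTENSIONS
    )
    jobs = []
    for i, path in enumerate(paths, start=1):
        job = JobDescription(
            image_path=path,
            output_path=(out / f"{path.stem}_labels.tif") if out else None,
            params=replace(params),
            job_id=i,
        )
        if not os.access(path, os.R_OK):
            job.status = "failed"
            job.error = "file is not readable"
        jobs.append(job)
    return jobs


def _process_job(job: JobDescription) -> dict:
    """Execute one job; must stay importable for process pools."""
    row = {
        "job_id": job.job_id,
        "image": str(job.image_path),
        "status": "failed",
        "error": None,
        "n_airspaces": np.nan,
        "n_intercepts": np.nan,
        "Lm_um": np.nan,
        "D0_um": np.nan,
        "D1_um": np.nan,
        "D2_um": np.nan,
    }
    if job.status == "failed":
        row["error"] = job.error or "failed at validation"
        return row
    try:
        image = iio.imread(job.image_path)
        labeled = segment_section(image, job.params)
        if job.output_path is not None:
            import tifffile

            job.output_path.parent.mkdir(parents=True, exist_ok=True)
            tifffile.imwrite(
                job.output_path, labeled.label_map.astype(np.uint16)
            )
        desc = compute_descriptors(labeled)
        row.update(
            status="done",
            n_airspaces=desc.n_airspaces,
            n_intercepts=desc.n_intercepts,
            Lm_um=desc.Lm_um,
            D0_um=desc.D0_um,
            D1_um=desc.D1_um,
            D2_um=desc.D2_um,
        )
    except Exception as exc:  # noqa: BLE001 - queue isolation contract
        row["error"] = f"{type(exc).__name__}: {exc}"
    return row


def run_queue(jobs: list[JobDescription], n_workers: int = 1) -> pd.DataFrame:
    """Process every job exactly once and return the sorted result table.

    With ``n_workers > 1`` jobs are distributed over a local process pool.
    The returned table is sorted by image path, so its content does not
    depend on the worker count or completion order.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    if not jobs:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    if n_workers == 1:
        rows = [_process_job(job) for job in jobs]
    else:
        with ProcessPoolExecutor(max_workers=n_workers) as pool:
            rows = list(pool.map(_process_job, jobs))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return table.sort_values("image", ignore_index=True)
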