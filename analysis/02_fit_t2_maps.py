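"""Fit T2 maps and compute T2 average images for every cohort session.

The pixel-wise decay fit is evaluated inside the volumetric analysis ROIs
(padded tumor bounding boxes from the label maps) — the region the
volumetry chain reads — and the T2 average uses the 45.8/62.5/79.2 ms
echoes everywhere.  Writes NIfTI maps under results/cohort/{t2map,t2avg}/.
"""

import sys
from pathlib import Path

import nibabel as nib
import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import load_config, session_ids

from t2flux import compute_t2_average, compute_t2_map, validate_stack
from t2flux import io as tio
from t2flux.phantom import TISSUE_LABELS
from t2flux.volumetry import auto_rois


def main() -> None:
    cfg = load_config()
    out = cfg["cohort_dir"]
    (out / "t2map").mkdir(parents=True, exist_ok=True)
    (out / "t2avg").mkdir(parents=True, exist_ok=True)

    n_fitted = 0
    for animal_id, week in session_ids(cfg):
        stack = validate_stack(out / "stacks" / f"{animal_id}_w{week}.nii")
        labels = tio.read_label_map(out / "labels" / f"{animal_id}_w{week}.nii")
        tumor = labels == TISSUE_LABELS["tumor"]

        box_mask = np.zeros(stack.spatial_shape, dtype=bool)
        for roi in auto_rois(np.zeros(stack.spatial_shape), tumor, 0.0, 1.0, pad=3):
            box_mask[roi.slice_index, roi.row0 : roi.row1, roi.col0 : roi.col1] = True

        t2map = compute_t2_map(stack, mask=box_mask)
        n_fitted += int(t2map.defined.sum())
        tio.write_t2_map(t2map, out / "t2map" / f"{animal_id}_w{week}.nii")

        avg = compute_t2_average(stack)
        nib.save(
            nib.Nifti1Image(avg.values.astype(np.float32), np.eye(4)),
            out / "t2avg" / f"{animal_id}_w{week}.nii",
        )
    n_sessions = cfg["n_animals"] * len(cfg["weeks"])
    print(f"fitted {n_fitted} pixels across {n_sessions} sessions; "
          f"maps in {out/'t2map'}, averages in {out/'t2avg'}")


if __name__ == "__main__":
    main()
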