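"""Per-dataset picking presets.

The five dataset presets bundle the published operating points for the EMPIAR
benchmark tomograms and the dNTPase sample (radius, contamination-mask
threshold/cleaning/dilation, detection z-width, final filtering threshold).
Two extra presets cover the shipped synthetic phantoms; their thresholds were
chosen from the foreground/background statistic distributions the test oracles
compute on those phantoms.
"""

from __future__ import annotations

from .pipeline import PickingConfig

__all__ = ["PRESETS", "get_preset"]

PRESETS: dict[str, PickingConfig] = {
    "empiar-10304": PickingConfig(
        pixel_size=2.10, radius_angstrom=100.0, mask_threshold_k=2.5,
        mask_min_component_voxels=125, mask_dilation_angstrom=70.0,
        detection_width_slices=128, filter_k=1.2,
    ),
    "empiar-10045": PickingConfig(
        pixel_size=2.17, radius_angstrom=90.0, mask_threshold_k=1.5,
        mask_min_component_voxels=125, mask_dilation_angstrom=70.0,
        detection_width_slices=128, filter_k=1.5,
    ),
    "empiar-10064": PickingConfig(
        pixel_size=2.62, radius_angstrom=70.0, mask_threshold_k=2.0,
        mask_min_component_voxels=125, mask_dilation_angstrom=100.0,
        detection_width_slices=128, filter_k=2.0,
    ),
    "empiar-10499": PickingConfig(
        pixel_size=1.70, radius_angstrom=90.0, mask_threshold_k=0.75,
        mask_min_component_voxels=125, mask_dilation_angstrom=70.0,
        detection_width_slices=128, filter_k=0.3,
    ),
    "dntpase": PickingConfig(
        pixel_size=1.35, radius_angstrom=55.0, mask_threshold_k=1.0,
        mask_min_component_voxels=125, mask_dilation_angstrom=70.0,
        detection_width_slices=32, filter_k=-0.1,
    ),
    # Synthetic-phantom presets (see tomopick.synth for the matching specs).
    "easy-invitro": PickingConfig(
        pixel_size=10.0, radius_angstrom=60.0, mask_threshold_k=5.0,
        mask_min_component_voxels=27, mask_dilation_angstrom=20.0,
        detection_width_slices=10**6, filter_k=1.2,
    ),
    "insitu-like": PickingConfig(
        pixel_size=10.0, radius_angstrom=60.0, mask_threshold_k=5.0,
        mask_min_component_voxels=27, mask_dilation_angstrom=20.0,
        detection_width_slices=10**6, filter_k=0.3,
        background_sigma_angstrom=100.0, lowpass_sigma_factor=0.7,
        use_background_criterion=True,
    ),
}


def get_preset(name: str) -> PickingConfig:
    try:
        return PRESETS[name].copy()
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None
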