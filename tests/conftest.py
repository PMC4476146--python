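import pytest

from livermet import CalibrationCurve, Modality


@pytest.fixture
def exact_fluor_curve() -> CalibrationCurve:
    """Noise-free fluorescence curve: signal = 100 * cells."""
    return CalibrationCurve(
        modality=Modality.FLUORESCENCE, slope=100.0, intercept=0.0,
        pearson_r=1.0, n_points=27,
    )


@pytest.fixture
def offset_fluor_curve() -> CalibrationCurve:
    """Fluorescence curve with background: signal = 250 * cells + 500."""
    return CalibrationCurve(
        modality=Modality.FLUORESCENCE, slope=250.0, intercept=500.0,
        pearson_r=1.0, n_points=27,
    )


@pytest.fixture
def lum_curve() -> CalibrationCurve:
    return CalibrationCurve(
        modality=Modality.LUMINESCENCE, slope=100.0, intercept=0.0,
        pearson_r=1.0, n_points=27,
    )
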