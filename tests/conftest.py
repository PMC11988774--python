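import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from bitewing.assignment import diagnose_scene
from bitewing.scene import Box, CariesDetection, Polygon, Severity
from bitewing.synthetic import SceneGenConfig, generate_scene


def rect_polygon(x0: float, y0: float, x1: float, y1: float) -> Polygon:
    return Polygon(((x0, y0), (x1, y0), (x1, y1), (x0, y1)))


def rect_caries(x0, y0, x1, y1, severity=Severity.RA, confidence=1.0) -> CariesDetection:
    return CariesDetection.from_polygon(severity, rect_polygon(x0, y0, x1, y1), confidence)


@pytest.fixture(scope="session")
def gen_scenes():
    """30 deterministic synthetic scenes with their ground-truth diagnoses."""
    cfg = SceneGenConfig(seed=7, lesion_rate=0.6)
    return [generate_scene(cfg, i) for i in range(30)]
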