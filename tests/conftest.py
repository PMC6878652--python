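import pytest
from hypothesis import HealthCheck, settings

from cghcall.design import ProbeDesign, RegionSpec, build_design

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def uniform_design(n: int, chrom: str = "1", spacing: int = 1000) -> ProbeDesign:
    """Single-region design of ``n`` evenly spaced probes on one chromosome."""
    return build_design(
        [RegionSpec("U", chrom, 1_000_000,
                    1_000_000 + (n - 1) * spacing, spacing, 0, n)],
        backbone_probes=0,
    )


@pytest.fixture(scope="session")
def small_design() -> ProbeDesign:
    """Compact two-region design plus a thin backbone (~250 probes)."""
    regions = [
        RegionSpec("A", "1", 1_000_000, 1_099_000, 1000, 0, 100),
        RegionSpec("B", "2", 5_000_000, 5_198_000, 2000, 0, 100),
    ]
    return build_design(regions, backbone_probes=50)


@pytest.fixture(scope="session")
def full_design() -> ProbeDesign:
    """The default 15K-style candidate-region design."""
    return build_design()


@pytest.fixture(scope="session")
def line_design() -> ProbeDesign:
    """Single-chromosome 10,000-probe design for calibration experiments."""
    return uniform_design(10_000)
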