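import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from micr_bids.fixtures import generate_dataset  # noqa: E402


@pytest.fixture(scope="session")
def png2d_dataset(tmp_path_factory):
    """A generated, read-only png2d tree shared across tests."""
    root = tmp_path_factory.mktemp("png2d") / "ds"
    generate_dataset("png2d", root, seed=0)
    return root


@pytest.fixture(scope="session")
def ometiff3d_dataset(tmp_path_factory):
    """A generated, read-only ometiff3d tree shared across tests."""
    root = tmp_path_factory.mktemp("ometiff3d") / "ds"
    generate_dataset("ometiff3d", root, seed=0)
    return root


@pytest.fixture
def make_dataset(tmp_path):
    """Factory for writable trees (mutation tests need a fresh copy each)."""

    def _make(template: str, seed: int = 0):
        root = tmp_path / f"{template}-{seed}"
        generate_dataset(template, root, seed=seed)
        return root

    return _make
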