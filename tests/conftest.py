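import pandas as pd
import pytest

from erfscan.io_formats import packaged_roster


@pytest.fixture(scope="session")
def roster() -> pd.DataFrame:
    return packaged_roster()


@pytest.fixture
def write_tmp(tmp_path):
    """Write text content to a named temp file and return its path."""

    def _write(name: str, content: str):
        p = tmp_path / name
        p.write_text(content)
        return p

    return _write
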