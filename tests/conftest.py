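import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from rejumet.simulate import (HumanDesignConfig, MouseDesignConfig,
                              generate_human_study, generate_mouse_study)


@pytest.fixture(scope="session")
def mouse_study():
    """Default mouse study at the reference arm sizes (seed fixed)."""
    config = MouseDesignConfig(seed=11)
    return generate_mouse_study(config)


@pytest.fixture(scope="session")
def human_study():
    """Default human dose-escalation study (seed fixed)."""
    config = HumanDesignConfig(seed=12)
    return generate_human_study(config)


@pytest.fixture()
def two_group_design():
    """3+3 two-group toy metadata and design."""
    from rejumet.differential import build_design

    meta = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "subject_id": [f"s{i}" for i in range(6)],
        "species": ["mouse"] * 6,
        "grp": ["a"] * 3 + ["b"] * 3,
    })
    return meta, build_design(meta, group="grp")
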