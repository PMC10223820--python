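import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from trescore.study_model import ProtocolTargets


@pytest.fixture
def targets() -> ProtocolTargets:
    """Protocol targets for a 08:00-21:00 baseline (targets 09:30/19:30)."""
    return ProtocolTargets(baseline_first=480.0, baseline_last=1260.0)


@pytest.fixture
def diary_file(tmp_path):
    """A small valid diary file for one participant, one day of which has
    a post-midnight snack."""
    path = tmp_path / "diary.csv"
    path.write_text(
        "participant,date,time,category,item,caloric\n"
        "P01,2022-03-01,08:00,breakfast,porridge,true\n"
        "P01,2022-03-01,13:00,lunch,salad,true\n"
        "P01,2022-03-01,20:30,dinner,pasta,true\n"
        "P01,2022-03-01,07:15,drink,black coffee,false\n"
        "P01,2022-03-02,09:00,breakfast,toast,true\n"
        "P01,2022-03-03,01:30,snack,crisps,true\n"
    )
    return path
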