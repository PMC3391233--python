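import json
from pathlib import Path

import pytest

from ccchsurvey.pipeline import SurveyConfig, make_demo, run_survey


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory) -> Path:
    """One synthetic demo bundle, generated once and shared read-only."""
    out = tmp_path_factory.mktemp("demo") / "bundle"
    make_demo(out, seed=11)
    return out


@pytest.fixture(scope="session")
def demo_report(demo_bundle) -> tuple[dict, dict, Path]:
    """(survey report, plan, results dir) for the shared demo bundle."""
    config = SurveyConfig.from_yaml(demo_bundle / "survey_config.yaml")
    report = run_survey(config)
    plan = json.loads((demo_bundle / "plan.json").read_text())
    return report, plan, Path(config.out_dir)
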