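import pandas as pd
import pytest

from canteen_cea import TrialConfig, generate_trial


@pytest.fixture(scope="session")
def small_config() -> TrialConfig:
    """A scaled-down trial that keeps the full two-arm structure."""
    return TrialConfig(
        n_intervention_schools=4, n_control_schools=3,
        students_per_school_mean=40, students_per_school_dispersion=8,
        n_per_protocol_schools=2, seed=7,
    )


@pytest.fixture(scope="session")
def small_trial(small_config):
    return generate_trial(small_config)


@pytest.fixture()
def toy_items() -> pd.DataFrame:
    """Six eligible orders for two students, hand-checkable."""
    rows = []

    def order(oid, student, period, energies, classes, **kw):
        for e, c in zip(energies, classes):
            rows.append(dict(
                order_id=oid, student_id=student, school_id="I01",
                arm="intervention", period=period, channel=kw.get("channel", "app"),
                break_type=kw.get("break_type", "lunch"),
                day_type=kw.get("day_type", "usual"), energy_kj=e,
                satfat_g=kw.get("satfat", 0.0), sugar_g=kw.get("sugar", 0.0),
                sodium_mg=0.0, classification=c))

    order(1, "A", "baseline", [400, 300, 300], ["everyday", "everyday", "occasional"])
    order(2, "A", "baseline", [1200, 800], ["everyday", "should_not_be_sold"])
    order(3, "A", "followup", [900], ["everyday"])
    order(4, "B", "baseline", [500, 500], ["occasional", "occasional"])
    return pd.DataFrame(rows)
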