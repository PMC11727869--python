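from datetime import datetime, timedelta

import pytest

from mi_phenotype.labs import InjuryCriteria, TroponinMeasurement, TroponinSeries

T0 = datetime(2015, 3, 1, 8, 0)


def make_series(values_at_hours, encounter_id="E1", t0=T0):
    """Series from (hours-offset, value ng/L) pairs; raw string is the value."""
    ms = [
        TroponinMeasurement(encounter_id, t0 + timedelta(hours=float(h)), f"{v:g}", float(v))
        for h, v in values_at_hours
    ]
    return TroponinSeries.build(encounter_id, ms)


@pytest.fixture
def criteria():
    return InjuryCriteria()
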