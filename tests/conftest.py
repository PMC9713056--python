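import pytest

from wisn import AWTComponents, StaffingRecord, compute_awt, compute_wisn_result
from wisn.io import load_kaduna_results, load_kaduna_standards


@pytest.fixture(scope="session")
def kaduna_standards():
    return load_kaduna_standards()


@pytest.fixture(scope="session")
def kaduna_results_frame():
    """Published per-facility table: available, required, printed gap and ratio."""
    return load_kaduna_results()


@pytest.fixture(scope="session")
def kaduna_results(kaduna_results_frame):
    """WISN results recomputed by the package from the published headcounts."""
    return [
        compute_wisn_result(
            StaffingRecord(
                facility=row.facility, cadre=row.cadre, available=int(row.available)
            ),
            int(row.required),
        )
        for row in kaduna_results_frame.itertuples(index=False)
    ]


@pytest.fixture(scope="session")
def awt_198():
    """A convenient reference year: 260 possible days minus 62 days off."""
    return compute_awt(
        AWTComponents(
            cadre="Nurse/Midwife",
            possible_working_days=260,
            public_holidays=15,
            official_leave=30,
            sick_leave=7,
            other_absence=10,
            hours_per_working_day=8,
        )
    )
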