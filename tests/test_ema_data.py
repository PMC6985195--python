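"""I/O, validation, endorsement screening, complete-case behavior."""

import numpy as np
import pandas as pd
import pytest

from emanet import (
    EmaDataset,
    EmaValidationError,
    InsufficientDataError,
    SymptomSchema,
    complete_cases,
    read_ema_csv,
    screen_endorsement,
    write_ema_csv,
)

SCHEMA3 = SymptomSchema.from_items(["Headache", "Fatigue", "Nausea"])


def make_csv(tmp_path, rows, header="person_id,timestamp,symptom,rating"):
    path = tmp_path / "ema.csv"
    path.write_text(header + "\n" + "\n".join(rows) + "\n")
    return path


class TestReadCsv:
    def test_single_prompt_pivots_to_one_row(self, tmp_path):
        path = make_csv(
            tmp_path,
            [
                "p1,2024-01-05T09:00:00,Headache,2",
                "p1,2024-01-05T09:00:00,Fatigue,0",
                "p1,2024-01-05T09:00:00,Nausea,1",
            ],
        )
        ds = read_ema_csv(path, SCHEMA3)["p1"]
        assert ds.Y.shape == (1, 3)
        assert ds.Y[0].tolist() == [2.0, 0.0, 1.0]

    @pytest.mark.parametrize(
        "bad_row, message",
        [
            ("p1,2024-01-05T09:00:00,Headache,7", "rating"),
            ("p1,2024-01-05T09:00:00,Headache,-1", "rating"),
            ("p1,not-a-date,Headache,2", "timestamp"),
            ("p1,2024-01-05T09:00:00,Wings,2", "schema"),
        ],
    )
    def test_invalid_rows_rejected(self, tmp_path, bad_row, message):
        path = make_csv(tmp_path, ["p1,2024-01-05T06:00:00,Headache,1", bad_row])
        with pytest.raises(EmaValidationError, match=message):
            read_ema_csv(path, SCHEMA3)

    def test_duplicate_prompt_symptom_rejected(self, tmp_path):
        path = make_csv(
            tmp_path,
            [
                "p1,2024-01-05T09:00:00,Headache,2",
                "p1,2024-01-05T09:00:00,Headache,3",
            ],
        )
        with pytest.raises(EmaValidationError, match="duplicate"):
            read_ema_csv(path, SCHEMA3)

    def test_missing_prompts_kept_and_counted(self, tmp_path, rng):
        # 100 prompts, 27 entirely unanswered (empty rating cells)
        missing = set(rng.choice(100, size=27, replace=False).tolist())
        rows = []
        for i in range(100):
            stamp = f"2024-01-01T{8 + (i % 5) * 3:02d}:00:00"
            day = pd.Timestamp("2024-01-01") + pd.Timedelta(days=i // 5)
            stamp = f"{day.date()}T{8 + (i % 5) * 3:02d}:00:00"
            for sym in SCHEMA3.items:
                val = "" if i in missing else "1"
                rows.append(f"p1,{stamp},{sym},{val}")
        ds = read_ema_csv(make_csv(tmp_path, rows), SCHEMA3)["p1"]
        assert ds.Y.shape == (100, 3)
        assert int(np.isnan(ds.Y).all(axis=1).sum()) == 27
        rep = screen_endorsement(ds, min_nonzero=1)
        assert rep.response_rate == pytest.approx(0.73)

    def test_round_trip_preserves_matrix_and_timestamps(self, tmp_path, rng):
        Y = rng.integers(0, 7, size=(12, 3)).astype(float)
        Y[3, :] = np.nan  # unanswered prompt
        Y[5, 1] = np.nan  # single skipped item
        ts = pd.date_range("2024-02-01 08:00", periods=12, freq="3h")
        ds = EmaDataset("p9", Y, ts, SCHEMA3)
        path = tmp_path / "rt.csv"
        write_ema_csv(ds, path)
        back = read_ema_csv(path, SCHEMA3)["p9"]
        np.testing.assert_array_equal(back.Y, ds.Y)
        assert (back.timestamps == ds.timestamps).all()
        assert back.symptoms == ds.symptoms


class TestDatasetInvariants:
    def test_rejects_out_of_range_and_noninteger_ratings(self):
        ts = pd.date_range("2024-01-01", periods=2, freq="3h")
        with pytest.raises(EmaValidationError):
            EmaDataset("p", [[8, 0, 0], [1, 1, 1]], ts, SCHEMA3)
        with pytest.raises(EmaValidationError):
            EmaDataset("p", [[1.5, 0, 0], [1, 1, 1]], ts, SCHEMA3)

    def test_rejects_duplicate_timestamps(self):
        ts = pd.DatetimeIndex(["2024-01-01 08:00"] * 2)
        with pytest.raises(EmaValidationError):
            EmaDataset("p", [[1, 0, 0], [1, 1, 1]], ts, SCHEMA3)


class TestScreenEndorsement:
    def ds(self, Y):
        Y = np.asarray(Y, dtype=float)
        ts = pd.date_range("2024-01-01 08:00", periods=len(Y), freq="3h")
        return EmaDataset("p", Y, ts, SCHEMA3)

    def test_all_zero_symptom_flagged(self):
        Y = np.zeros((20, 3))
        Y[:, 0] = [1, 3] * 10
        rep = screen_endorsement(self.ds(Y))
        assert rep.status["Headache"] == "endorsed"
        assert rep.status["Fatigue"] == "insufficient_variance"
        assert rep.status["Nausea"] == "insufficient_variance"

    def test_single_nonzero_in_100_flagged_under_count_rule(self):
        Y = np.zeros((100, 3))
        Y[:, 0] = [1, 3] * 50
        Y[-1, 1] = 1  # one nonzero rating out of 100
        rep = screen_endorsement(self.ds(Y), min_nonzero=3)
        assert rep.n_nonzero["Fatigue"] == 1
        assert rep.status["Fatigue"] == "insufficient_variance"

    def test_alternating_ratings_endorsed(self):
        Y = np.tile([[1, 1, 1], [3, 3, 3]], (10, 1))
        rep = screen_endorsement(self.ds(Y))
        assert set(rep.status.values()) == {"endorsed"}

    def test_invariant_to_row_order(self, rng):
        Y = rng.integers(0, 7, size=(30, 3)).astype(float)
        perm = rng.permutation(30)
        ts = pd.date_range("2024-01-01 08:00", periods=30, freq="3h")
        a = screen_endorsement(EmaDataset("p", Y, ts, SCHEMA3))
        b = screen_endorsement(EmaDataset("p", Y[perm], ts, SCHEMA3))
        assert a.status == b.status
        assert a.n_nonzero == b.n_nonzero

    def test_too_few_rows_raises(self):
        Y = np.full((5, 3), np.nan)
        Y[0] = [1, 2, 3]
        with pytest.raises(InsufficientDataError):
            screen_endorsement(self.ds(Y))


class TestCompleteCases:
    def make(self, n=100, n_missing=27):
        Y = np.tile([1.0, 2.0, 3.0], (n, 1))
        Y[:n_missing, :] = np.nan
        ts = pd.date_range("2024-01-01 08:00", periods=n, freq="3h")
        return EmaDataset("p", Y, ts, SCHEMA3)

    def test_drops_missing_rows(self):
        out = complete_cases(self.make(), ["Headache", "Fatigue"])
        assert out.n_obs == 73

    def test_identity_when_no_missing(self):
        ds = self.make(n_missing=0)
        out = complete_cases(ds)
        np.testing.assert_array_equal(out.Y, ds.Y)
        assert (out.timestamps == ds.timestamps).all()

    def test_idempotent_and_subset(self):
        once = complete_cases(self.make())
        twice = complete_cases(once)
        np.testing.assert_array_equal(once.Y, twice.Y)

    def test_all_missing_symptom_raises(self):
        ds = self.make(n_missing=0)
        ds.Y[:, 2] = np.nan
        with pytest.raises(InsufficientDataError):
            complete_cases(ds, ["Nausea"])
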