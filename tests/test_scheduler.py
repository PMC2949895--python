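import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import paralign.scheduler as sched
from paralign import (
    SchedulerConfig,
    compare_policies,
    default_params,
    gen_task_costs,
    run_distance_phase,
    schedule_fixed_chunk,
    schedule_insta,
    store_create,
)
from paralign.diststore import n_pairs
from paralign.scheduler import (
    SerialExecutor,
    TaskFailedError,
    ThreadedExecutor,
    tasks_for_seqset,
    tasks_from_costs,
)

from tests._oracles import optimal_makespan


def insta_cfg(m):
    return SchedulerConfig(policy="insta", n_workers=m)


def chunk_cfg(m, k):
    return SchedulerConfig(policy="fixed_chunk", n_workers=m, chunk_size=k)


class TestInsta:
    def test_uniform_costs_balance_perfectly(self):
        trace = schedule_insta(tasks_from_costs([1.0] * 6), insta_cfg(2))
        assert trace.makespan == 3.0 and trace.idle_fraction == 0.0

    def test_long_task_pins_one_worker(self):
        trace = schedule_insta(tasks_from_costs([5, 1, 1, 1, 1, 1]), insta_cfg(2))
        assert trace.makespan == 5.0
        assert [P for P, _, _ in trace.assignments[0]] == [0]
        assert [P for P, _, _ in trace.assignments[1]] == [1, 2, 3, 4, 5]

    def test_single_worker_serializes(self, rng):
        costs = rng.uniform(0.1, 3.0, size=17).tolist()
        trace = schedule_insta(tasks_from_costs(costs), insta_cfg(1))
        assert trace.makespan == pytest.approx(sum(costs))

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            schedule_insta(tasks_from_costs([1.0, -0.5]), insta_cfg(2))


class TestFixedChunk:
    def test_round_robin_chunks(self):
        trace = schedule_fixed_chunk(tasks_from_costs([5, 1, 1, 1, 1, 1]), chunk_cfg(2, 3))
        assert trace.makespan == 7.0
        assert trace.busy_times == [7.0, 3.0]

    def test_degenerate_chunk_serializes_on_worker_zero(self):
        costs = [2.0, 1.0, 4.0]
        trace = schedule_fixed_chunk(tasks_from_costs(costs), chunk_cfg(2, 10))
        assert trace.makespan == pytest.approx(sum(costs))
        assert trace.busy_times[1] == 0.0

    def test_uniform_unit_chunks_match_insta(self):
        costs = [1.0] * 12
        ms_chunk = schedule_fixed_chunk(tasks_from_costs(costs), chunk_cfg(3, 1)).makespan
        ms_insta = schedule_insta(tasks_from_costs(costs), insta_cfg(3)).makespan
        assert ms_chunk == ms_insta == 4.0


class TestComparePolicies:
    def test_uniform_costs_equal_speedups_at_chunk_one(self):
        rows = compare_policies([1.0] * 12, [3], chunk_size=1)
        speedups = {r["policy"]: r["speedup"] for r in rows}
        assert speedups["insta"] == speedups["fixed_chunk"] == 3.0

    def test_hand_simulated_example(self):
        rows = compare_policies([5, 1, 1, 1, 1, 1], [2], chunk_size=3)
        by_policy = {r["policy"]: r for r in rows}
        assert by_policy["insta"]["speedup"] == pytest.approx(2.0)
        assert by_policy["fixed_chunk"]["speedup"] == pytest.approx(10 / 7)

    @given(st.lists(st.floats(0.01, 10), min_size=1, max_size=30),
           st.integers(1, 5))
    def test_makespan_lower_bound(self, costs, m):
        for row in compare_policies(costs, [m]):
            assert row["makespan"] >= max(max(costs), sum(costs) / m) - 1e-9


class TestSchedulingBounds:
    @given(st.lists(st.floats(0.01, 5), min_size=1, max_size=8),
           st.integers(1, 3))
    @settings(max_examples=60)
    def test_insta_within_graham_bound_of_optimum(self, costs, m):
        """Greedy list scheduling is within (2 - 1/m) of the brute-force
        optimal assignment."""
        ms = schedule_insta(tasks_from_costs(costs), insta_cfg(m)).makespan
        opt = optimal_makespan(costs, m)
        assert ms <= (2 - 1 / m) * opt + 1e-9

    def test_insta_at_most_chunk_plus_max_task(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 40))
            costs = gen_task_costs(n, "pareto", seed=int(rng.integers(2**31)),
                                   alpha=1.5).tolist()
            m = int(rng.integers(1, 9))
            k = int(rng.integers(1, max(2, n // 2)))
            insta = schedule_insta(tasks_from_costs(costs), insta_cfg(m)).makespan
            chunk = schedule_fixed_chunk(tasks_from_costs(costs), chunk_cfg(m, k)).makespan
            assert insta <= chunk + max(costs) + 1e-9


class TestTrace:
    def test_invariants_and_tsv_export(self, tmp_path, rng):
        costs = rng.uniform(0.1, 2.0, size=25).tolist()
        trace = schedule_insta(tasks_from_costs(costs), insta_cfg(4))
        trace.validate()
        assert sum(len(w) for w in trace.assignments) == 25
        assert 0.0 <= trace.idle_fraction <= 1.0
        out = tmp_path / "trace.tsv"
        trace.to_tsv(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "worker\tP\tstart\tfinish" and len(lines) == 26


class TestDistancePhase:
    def test_single_pair(self, small_family, protein_params):
        pair = type(small_family)(small_family.records[:2])
        store = run_distance_phase(pair, protein_params, store_create(2))
        assert 0.0 <= store.get(0, 1) <= 1.0

    def test_task_counter_matches_closed_form(self, small_family, protein_params):
        executor = SerialExecutor()
        run_distance_phase(small_family, protein_params, store_create(small_family.N),
                           executor=executor)
        assert executor.tasks_done == n_pairs(small_family.N)

    def test_store_identical_across_configs(self, small_family, protein_params, tmp_path):
        """Distance results must be schedule-invariant: policy, worker count
        and backend must not change a single byte."""
        reference = None
        for policy in ("insta", "fixed_chunk"):
            for workers in (1, 4):
                for mode in ("memory", "disk"):
                    store = store_create(small_family.N, mode,
                                         tmp_path / f"{policy}-{workers}-{mode}")
                    cfg = SchedulerConfig(policy=policy, n_workers=workers)
                    run_distance_phase(small_family, protein_params, store, config=cfg)
                    cells = store.cells().tobytes()
                    store.close()
                    if reference is None:
                        reference = cells
                    assert cells == reference

    def test_failed_task_requeued_once(self, small_family, protein_params, monkeypatch):
        real = sched.pairwise_distance
        failures = {"left": 3}

        def flaky(a, b, params):
            if failures["left"] > 0:
                failures["left"] -= 1
                raise RuntimeError("transient worker failure")
            return real(a, b, params)

        monkeypatch.setattr(sched, "pairwise_distance", flaky)
        store = run_distance_phase(small_family, protein_params,
                                   store_create(small_family.N))
        assert store.is_complete()

    def test_persistent_failure_names_the_pair(self, small_family, protein_params,
                                               monkeypatch):
        def broken(a, b, params):
            raise RuntimeError("worker gone")

        monkeypatch.setattr(sched, "pairwise_distance", broken)
        with pytest.raises(TaskFailedError, match="P=0"):
            run_distance_phase(small_family, protein_params,
                               store_create(small_family.N))

    def test_threaded_executor_fills_store(self, small_family, protein_params):
        store = run_distance_phase(small_family, protein_params,
                                   store_create(small_family.N),
                                   executor=ThreadedExecutor(3))
        assert store.is_complete()


def test_simulated_executor_records_trace(small_family, protein_params):
    tasks = tasks_for_seqset(small_family)
    cfg = SchedulerConfig(policy="insta", n_workers=4)
    ex = sched.SimulatedExecutor(cfg, costs=[t.cost for t in tasks])
    store = run_distance_phase(small_family, protein_params,
                               store_create(small_family.N), executor=ex)
    assert store.is_complete()
    assert ex.trace is not None and ex.trace.makespan > 0
    ex.trace.validate()


def test_cost_model_scaled_to_unit_mean(small_family):
    tasks = tasks_for_seqset(small_family)
    assert np.mean([t.cost for t in tasks]) == pytest.approx(1.0)
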