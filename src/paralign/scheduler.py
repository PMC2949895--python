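"""Master-worker distribution of pair tasks.

Two policies are modelled:

* **insta** — dynamic self-scheduling: each worker holds one task at a
  time and requests the next unassigned task the moment it goes idle
  (greedy list scheduling in canonical pair order).
* **fixed_chunk** — the static policy of classic MPI aligners: tasks are
  pre-partitioned into consecutive chunks dealt round-robin to workers
  before execution starts.

A discrete-event simulator produces per-worker traces (makespan, busy and
idle time) from a task-cost model; real execution goes through a small
executor contract so the distance phase is schedule-invariant: whatever
the policy, worker count or interleaving, the master writes each distance
keyed by (i, j) and the final store is bit-identical.
"""
from __future__ import annotations

import heapq
import math
from concurrent.futures import FIRST_COMPLETED, ThreadPoolExecutor, wait
from dataclasses import dataclass
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple


from .diststore import DistanceStore, iter_pairs, n_pairs
from .io_formats import SequenceSet
from .pairwise import AlignParams, pairwise_distance


class TaskFailedError(RuntimeError):
    pass


@dataclass(frozen=True)
class PairTask:
    """A unit of pairwise work: pair rank P over sequence indices (i, j)
    with a non-negative cost (simulated duration or measured time)."""

    P: int
    i: int
    j: int
    cost: float = 0.0


@dataclass
class SchedulerConfig:
    policy: str = "insta"
    n_workers: int = 1
    chunk_size: Optional[int] = None  # fixed_chunk only; insta ignores it
    seed: int = 0

    def __post_init__(self):
        if self.policy not in {"insta", "fixed_chunk"}:
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.chunk_size is not None and self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")


def default_chunk_size(n_tasks: int, n_workers: int) -> int:
    return max(1, math.ceil(n_tasks / (5 * n_workers)))


@dataclass
class ScheduleTrace:
    """Per-worker execution log: ordered (P, start, finish) triples."""

    assignments: List[List[Tuple[int, float, float]]]
    policy: str

    @property
    def n_workers(self) -> int:
        return len(self.assignments)

    @property
    def makespan(self) -> float:
        finishes = [iv[2] for w in self.assignments for iv in w]
        return max(finishes) if finishes else 0.0

    @property
    def busy_times(self) -> List[float]:
        return [sum(f - s for _, s, f in w) for w in self.assignments]

    @property
    def idle_fraction(self) -> float:
        ms = self.makespan
        if ms == 0.0:
            return 0.0
        return 1.0 - sum(self.busy_times) / (self.n_workers * ms)

    def validate(self) -> None:
        seen = set()
        for w in self.assignments:
            prev_finish = 0.0
            for P, s, f in w:
                if P in seen:
                    raise AssertionError(f"task {P} scheduled twice")
                seen.add(P)
                if s < prev_finish - 1e-12 or f < s:
                    raise AssertionError(f"overlapping intervals on a worker (task {P})")
                prev_finish = f

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("worker\tP\tstart\tfinish\n")
            for w, ivs in enumerate(self.assignments):
                for P, s, f in ivs:
                    fh.write(f"{w}\t{P}\t{s:.9g}\t{f:.9g}\n")


def _check_costs(tasks: Sequence[PairTask]) -> None:
    if not tasks:
        raise ValueError("task list is empty")
    for t in tasks:
        if t.cost < 0:
            raise ValueError(f"task {t.P} has negative cost {t.cost}")


def schedule_insta(tasks: Sequence[PairTask], config: SchedulerConfig) -> ScheduleTrace:
    """Simulate dynamic self-scheduling: at t=0 each worker receives one
    task in canonical order; a finishing worker immediately receives the
    next unassigned task.  Ties break toward the lowest worker index."""
    _check_costs(tasks)
    if config.policy != "insta":
        raise ValueError("config.policy must be 'insta'")
    m = config.n_workers
    assignments: List[List[Tuple[int, float, float]]] = [[] for _ in range(m)]
    heap = [(0.0, w) for w in range(m)]  # (ready time, worker index)
    heapq.heapify(heap)
    for task in tasks:
        t, w = heapq.heappop(heap)
        assignments[w].append((task.P, t, t + task.cost))
        heapq.heappush(heap, (t + task.cost, w))
    trace = ScheduleTrace(assignments, "insta")
    trace.validate()
    return trace


def schedule_fixed_chunk(tasks: Sequence[PairTask], config: SchedulerConfig) -> ScheduleTrace:
    """Simulate static chunking: consecutive chunks of ``chunk_size`` tasks
    are dealt round-robin to workers before execution starts."""
    _check_costs(tasks)
    if config.policy != "fixed_chunk":
        raise ValueError("config.policy must be 'fixed_chunk'")
    m = config.n_workers
    k = config.chunk_size or default_chunk_size(len(tasks), m)
    per_worker: List[List[PairTask]] = [[] for _ in range(m)]
    for c, start in enumerate(range(0, len(tasks), k)):
        per_worker[c % m].extend(tasks[start : start + k])
    assignments: List[List[Tuple[int, float, float]]] = [[] for _ in range(m)]
    for w, wtasks in enumerate(per_worker):
        t = 0.0
        for task in wtasks:
            assignments[w].append((task.P, t, t + task.cost))
            t += task.cost
    trace = ScheduleTrace(assignments, "fixed_chunk")
    trace.validate()
    return trace


def simulate(tasks: Sequence[PairTask], config: SchedulerConfig) -> ScheduleTrace:
    if config.policy == "insta":
        return schedule_insta(tasks, config)
    return schedule_fixed_chunk(tasks, config)


def tasks_from_costs(costs: Sequence[float]) -> List[PairTask]:
    """Wrap a bare cost list as tasks (P doubles as the pair rank)."""
    return [PairTask(P=k, i=0, j=k + 1, cost=float(c)) for k, c in enumerate(costs)]


def tasks_for_seqset(seqset: SequenceSet, unit_mean: bool = True) -> List[PairTask]:
    """Canonical task list for a sequence set with the O(m*n) DP cost model
    cost(i, j) = len_i * len_j, scaled to unit mean."""
    lengths = [len(rec) for rec in seqset]
    tasks = [PairTask(P, i, j, float(lengths[i] * lengths[j]))
             for P, i, j in iter_pairs(seqset.N)]
    if unit_mean and tasks:
        mean = sum(t.cost for t in tasks) / len(tasks)
        if mean > 0:
            tasks = [PairTask(t.P, t.i, t.j, t.cost / mean) for t in tasks]
    return tasks


def compare_policies(task_costs: Sequence[float], n_workers_list: Sequence[int],
                     chunk_size: Optional[int] = None) -> List[Dict[str, float]]:
    """Makespan/speedup/idle table for both policies over a worker sweep.
    Speedup is serial work divided by makespan."""
    tasks = tasks_from_costs(task_costs)
    serial = sum(t.cost for t in tasks)
    rows: List[Dict[str, float]] = []
    for m in n_workers_list:
        for policy in ("insta", "fixed_chunk"):
            cfg = SchedulerConfig(policy=policy, n_workers=m,
                                  chunk_size=chunk_size if policy == "fixed_chunk" else None)
            trace = simulate(tasks, cfg)
            ms = trace.makespan
            rows.append({
                "n_workers": m,
                "policy": policy,
                "makespan": ms,
                "speedup": serial / ms if ms > 0 else 1.0,
                "idle_fraction": trace.idle_fraction,
            })
    return rows


# ---------------------------------------------------------------------------
# Execution backends


class SerialExecutor:
    """In-process executor: the degenerate one-worker pool."""

    n_workers = 1

    def __init__(self):
        self.tasks_done = 0

    def run(self, tasks: Iterable[PairTask], fn: Callable[[PairTask], float]):
        for task in tasks:
            try:
                result = fn(task)
            except Exception as exc:
                yield task, exc
                continue
            yield task, result
            self.tasks_done += 1


class ThreadedExecutor:
    """Worker pool over threads honoring the self-scheduling contract:
    each worker holds one task and requests the next when it finishes."""

    def __init__(self, n_workers: int):
        self.n_workers = n_workers
        self.tasks_done = 0

    def run(self, tasks: Iterable[PairTask], fn: Callable[[PairTask], float]):
        it = iter(tasks)
        with ThreadPoolExecutor(max_workers=self.n_workers) as pool:
            pending = {}
            for _ in range(self.n_workers):
                task = next(it, None)
                if task is None:
                    break
                pending[pool.submit(fn, task)] = task
            while pending:
                done, _ = wait(pending, return_when=FIRST_COMPLETED)
                for fut in done:
                    task = pending.pop(fut)
                    exc = fut.exception()
                    if exc is not None:
                        yield task, exc
                    else:
                        yield task, fut.result()
                        self.tasks_done += 1
                    nxt = next(it, None)
                    if nxt is not None:
                        pending[pool.submit(fn, nxt)] = nxt


def run_distance_phase(
    seqset: SequenceSet,
    params: AlignParams,
    store: DistanceStore,
    config: Optional[SchedulerConfig] = None,
    executor=None,
    progress: Optional[Callable[[int, int], None]] = None,
) -> DistanceStore:
    """Stage (1): compute every pairwise distance and write it to the store.

    The master owns all writes, keyed by (i, j); a failed task is re-queued
    once before the job errors out naming its pair rank P.  ``progress`` is
    called as progress(done, total).
    """
    if store.N != seqset.N:
        raise ValueError(f"store sized for N={store.N} but set has N={seqset.N}")
    config = config or SchedulerConfig()
    if executor is None:
        executor = (ThreadedExecutor(config.n_workers) if config.n_workers > 1
                    else SerialExecutor())
    total = n_pairs(seqset.N)
    seqs = [rec.residues for rec in seqset]

    def compute(task: PairTask) -> float:
        return pairwise_distance(seqs[task.i], seqs[task.j], params)

    tasks = (PairTask(P, i, j) for P, i, j in iter_pairs(seqset.N))
    done = 0
    retry: List[PairTask] = []
    for task, result in executor.run(tasks, compute):
        if isinstance(result, BaseException):
            retry.append(task)
            continue
        store.put(task.i, task.j, result)
        done += 1
        if progress is not None:
            progress(done, total)
    for task in retry:
        try:
            d = compute(task)
        except Exception as exc:
            raise TaskFailedError(f"pair task P={task.P} failed twice: {exc}") from exc
        store.put(task.i, task.j, d)
        done += 1
        if progress is not None:
            progress(done, total)
    if done != total:
        raise TaskFailedError(f"dispatched {done} of {total} pair tasks")
    return store


class SimulatedExecutor:
    """Cost-model execution: computes real distances serially while
    logging the schedule a worker pool would have followed under the
    configured policy."""

    def __init__(self, config: SchedulerConfig, costs: Optional[Sequence[float]] = None):
        self.config = config
        self.costs = costs
        self.n_workers = config.n_workers
        self.tasks_done = 0
        self.trace: Optional[ScheduleTrace] = None

    def run(self, tasks: Iterable[PairTask], fn: Callable[[PairTask], float]):
        tasks = list(tasks)
        costs = self.costs if self.costs is not None else [1.0] * len(tasks)
        timed = [PairTask(t.P, t.i, t.j, float(c)) for t, c in zip(tasks, costs)]
        self.trace = simulate(timed, self.config)
        for task in tasks:
            yield task, fn(task)
            self.tasks_done += 1
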