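"""Peak-memory probing, the affine memory model, and the files-level K1."""

import math
import shlex
import sys

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pmffrc.errors import BackendError, BudgetError, ConfigError
from pmffrc.memory_model import (
    BackendSpec,
    MemoryProbe,
    builtin_backends,
    estimate_cpm,
    files_level_K,
    get_backend,
    load_backends,
    measure_peak_memory,
)

MB = 10**6


def probe(y1, y2, v=2, x1=1, x2=3):
    return MemoryProbe(x1=x1, x2=x2, y_peak_1=y1, y_peak_2=y2, v=v)


class TestEstimate:
    def test_zero_slope_means_constant_memory(self):
        est = estimate_cpm(probe(500, 500), total_records=10**9)
        assert est.y_cpm == est.y_res == 500 and est.y_reads == 0

    def test_direct_evaluation(self):
        # v=2, x1=1, x2=3: slope = |108-100| MB / (2*2) = 2 MB/record
        est = estimate_cpm(probe(100 * MB, 108 * MB), total_records=50)
        assert est.slope_per_read == 2 * MB
        assert est.y_reads == 100 * MB
        assert est.y_cpm == 200 * MB

    def test_empty_collection_keeps_intercept(self):
        est = estimate_cpm(probe(100 * MB, 108 * MB), total_records=0)
        assert est.y_cpm == est.y_res == 100 * MB

    def test_probe_requires_x2_above_x1(self):
        with pytest.raises(ValueError):
            MemoryProbe(x1=5, x2=5, y_peak_1=1, y_peak_2=2, v=1)

    @given(
        a=st.integers(0, 10**9),
        b=st.integers(0, 10**4),
        v=st.integers(1, 50),
        x1=st.integers(1, 100),
        dx=st.integers(1, 10**4),
        total=st.integers(0, 10**7),
    )
    def test_affine_model_recovered_exactly(self, a, b, v, x1, dx, total):
        """Peaks injected from peak = a + b*records give back slope b exactly
        and an estimate affine in total_records with intercept y_peak_1."""
        x2 = x1 + dx
        y1 = a + b * v * x1
        y2 = a + b * v * x2
        est = estimate_cpm(probe(y1, y2, v=v, x1=x1, x2=x2), total)
        assert est.slope_per_read == pytest.approx(b)
        assert est.y_res == y1
        assert est.y_cpm == pytest.approx(y1 + b * total)


class TestFilesLevelK:
    def test_exact_fit_gives_one_cluster(self):
        # slope (104-100)/4 = 1 B/read; y_res=100, y_reads=100; u=200 -> K1=1
        est = estimate_cpm(probe(100, 104), total_records=100)
        assert est.y_reads == 100
        assert files_level_K(est, u_ram=200, beta=1.0) == 1

    def test_direct_ceiling(self):
        # y_res=0, y_reads=380, beta=1.05, u=100 -> ceil(3.99) = 4
        est = estimate_cpm(probe(0, 4), total_records=380)
        assert est.y_reads == 380
        assert files_level_K(est, u_ram=100, beta=1.05) == 4

    def test_floor_of_one_when_no_read_memory(self):
        est = estimate_cpm(probe(50, 50), total_records=1000)
        assert files_level_K(est, u_ram=100, beta=1.0) == 1

    def test_infeasible_budget(self):
        est = estimate_cpm(probe(100, 108), total_records=10)
        with pytest.raises(BudgetError, match="raise -u"):
            files_level_K(est, u_ram=100, beta=1.0)

    @given(
        y_res=st.integers(0, 1000),
        slope=st.integers(0, 500),
        total=st.integers(0, 10**5),
        extra=st.integers(1, 10**6),
        beta=st.floats(0.05, 4.0),
    )
    def test_matches_bruteforce_ceiling(self, y_res, slope, total, extra, beta):
        """K1 from probe-derived estimates equals a direct ceiling computation."""
        est = estimate_cpm(
            probe(y_res, y_res + slope * 4, v=2, x1=1, x2=3), total_records=total
        )
        u_ram = y_res + extra
        got = files_level_K(est, u_ram, beta)
        expect = max(1, math.ceil(beta * est.y_reads / (u_ram - est.y_res)))
        assert got == expect

    def test_monotonicity(self):
        est = estimate_cpm(probe(100, 900, v=1, x1=1, x2=3), total_records=5000)
        ks_u = [files_level_K(est, u, 1.0) for u in (200, 400, 800, 10**9)]
        assert ks_u == sorted(ks_u, reverse=True)
        ks_b = [files_level_K(est, 500, b) for b in (0.1, 0.5, 1.0, 2.0)]
        assert ks_b == sorted(ks_b)
        ks_t = [
            files_level_K(estimate_cpm(probe(100, 900, v=1, x1=1, x2=3), t), 500, 1.0)
            for t in (0, 10, 1000, 10**6)
        ]
        assert ks_t == sorted(ks_t)


def _alloc_backend(mib: int, hold: float = 0.5) -> BackendSpec:
    """Mock compressor allocating a known buffer, holding it, then copying input."""
    code = (
        "import sys,time,shutil;"
        f"buf=bytearray({mib}*1024*1024);"
        f"time.sleep({hold});"
        "shutil.copyfile(sys.argv[1],sys.argv[2])"
    )
    return BackendSpec(
        name="alloc",
        compress_template=f"{shlex.quote(sys.executable)} -c {shlex.quote(code)} {{input}} {{output}}",
        decompress_template="cp {input} {output}",
    )


class TestMeasurePeak:
    def test_known_allocation_observed(self, tmp_path):
        src = tmp_path / "in.txt"
        src.write_text("A" * 1000)
        peak = measure_peak_memory(_alloc_backend(64), src, tmp_path)
        base = 64 * 1024 * 1024
        assert base * 0.9 <= peak <= base * 1.1 + 120 * 1024 * 1024  # + interpreter

    def test_repeatable_within_polling_tolerance(self, tmp_path):
        src = tmp_path / "in.txt"
        src.write_text("A" * 1000)
        p1 = measure_peak_memory(_alloc_backend(32, hold=0.3), src, tmp_path)
        p2 = measure_peak_memory(_alloc_backend(32, hold=0.3), src, tmp_path)
        assert abs(p1 - p2) <= 0.25 * max(p1, p2)

    def test_failing_backend_raises(self, tmp_path):
        src = tmp_path / "in.txt"
        src.write_text("x")
        bad = BackendSpec(
            name="bad", compress_template="false {input} {output}",
            decompress_template="false {input} {output}",
        )
        with pytest.raises(BackendError, match="exited with status"):
            measure_peak_memory(bad, src, tmp_path)

    def test_missing_binary_is_config_error(self, tmp_path):
        src = tmp_path / "in.txt"
        src.write_text("x")
        ghost = BackendSpec(
            name="ghost",
            compress_template="/no/such/binary_xyz {input} {output}",
            decompress_template="/no/such/binary_xyz {input} {output}",
        )
        with pytest.raises(ConfigError, match="binary not found"):
            measure_peak_memory(ghost, src, tmp_path)


class TestBackendSpec:
    def test_template_must_have_placeholders_once(self):
        with pytest.raises(ConfigError, match="exactly once"):
            BackendSpec(name="x", compress_template="cc {input}", decompress_template="dd {input} {output}")
        with pytest.raises(ConfigError, match="beta"):
            BackendSpec(name="x", compress_template="cc {input} {output}",
                        decompress_template="dd {input} {output}", beta=0)

    def test_builtin_generic_round_trips(self, tmp_path):
        spec = builtin_backends()["generic"]
        src = tmp_path / "in.txt"
        src.write_bytes(b"ACGT\n" * 500)
        comp, out = tmp_path / "c.xz", tmp_path / "out.txt"
        import subprocess

        subprocess.run(spec.compress_command(src, comp), check=True)
        subprocess.run(spec.decompress_command(comp, out), check=True)
        assert out.read_bytes() == src.read_bytes()
        assert comp.stat().st_size < src.stat().st_size

    def test_load_backends_from_ini(self, tmp_path):
        ini = tmp_path / "backends.ini"
        ini.write_text(
            "[mycomp]\ncompress = cc {input} {output}\n"
            "decompress = dd {input} {output}\nbeta = 0.5\nthreads = 4\n"
        )
        specs = load_backends(ini)
        assert specs["mycomp"].beta == 0.5 and specs["mycomp"].threads == 4
        resolved = get_backend("mycomp", config_path=ini, beta=2.0)
        assert resolved.beta == 2.0
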