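import pytest

import drugconnect as dc
from drugconnect.synthgen import SynthConfig, generate


@pytest.fixture(scope="session")
def synth_default(tmp_path_factory):
    """Default synthetic benchmark (seed 0): file paths, truth, built profiles."""
    out = tmp_path_factory.mktemp("synth_default")
    paths, truth = generate(SynthConfig(seed=0), out)
    profiles, summary = dc.build_map(paths["evidence"], paths["ppi"])
    return {
        "paths": paths,
        "truth": truth,
        "profiles": profiles,
        "summary": summary,
        "indications": dc.read_indications(paths["indications"]),
        "signatures": dc.read_signatures(paths["signatures"]),
    }


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
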