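import pytest

from genorepo.fixtures import FixtureSpec, generate_fixture_repo


@pytest.fixture(scope="session")
def fixture_spec():
    # 6 organisms, 2 versions each: exercises representative scoping;
    # planted annotation K09999 separates the halophile/mesophile tag groups
    return FixtureSpec(n_organisms=6, versions_per_organism=2, seed=7)


@pytest.fixture(scope="session")
def fixture_repo(tmp_path_factory, fixture_spec):
    root = tmp_path_factory.mktemp("fixture") / "repo"
    report = generate_fixture_repo(fixture_spec, root)
    assert report.ok, report
    return root


@pytest.fixture(scope="session")
def tag_groups(fixture_repo):
    from genorepo import resolve_selector

    return (
        sorted(resolve_selector("@tag:halophile", fixture_repo)),
        sorted(resolve_selector("@tag:mesophile", fixture_repo)),
    )
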