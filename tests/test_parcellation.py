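import numpy as np
import pandas as pd
import pytest

from rsnvar.errors import ValidationError
from rsnvar.parcellation import (ParcellatedSeries, RoiAtlas,
                                 concatenate_runs, extract_series,
                                 pet_roi_means, read_atlas, read_pet_map,
                                 read_series, write_atlas, write_pet_map,
                                 write_series, PetRoiMap)
from rsnvar.synthetic import SimulationConfig, make_atlas


@pytest.fixture()
def image_atlas():
    cfg = SimulationConfig(n_regions=12, n_networks=2,
                           regions_per_network=4)
    return make_atlas(cfg, with_image=True)


class TestAtlasRoundTrip:
    def test_write_read_identical(self, image_atlas, tmp_path):
        paths = (tmp_path / "labels.nii", tmp_path / "labels.tsv",
                 tmp_path / "templates.tsv")
        write_atlas(image_atlas, *paths)
        back = read_atlas(*paths)
        assert np.array_equal(back.region_ids, image_atlas.region_ids)
        assert back.rsn_templates == image_atlas.rsn_templates
        assert np.array_equal(back.label_image, image_atlas.label_image)

    def test_duplicate_region_id_rejected(self, tmp_path):
        (tmp_path / "labels.tsv").write_text(
            "region_id\tname\n1\ta\n1\tb\n")
        (tmp_path / "templates.tsv").write_text("network\tregion_id\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_atlas(None, tmp_path / "labels.tsv",
                       tmp_path / "templates.tsv")

    def test_unknown_template_id_named_in_error(self, tmp_path):
        (tmp_path / "labels.tsv").write_text(
            "region_id\tname\n1\ta\n2\tb\n")
        (tmp_path / "templates.tsv").write_text(
            "network\tregion_id\nDMN\t9999\n")
        with pytest.raises(ValidationError, match="9999"):
            read_atlas(None, tmp_path / "labels.tsv",
                       tmp_path / "templates.tsv")


class TestAtlasInvariants:
    def test_too_few_regions(self):
        with pytest.raises(ValidationError):
            RoiAtlas(region_ids=np.array([1]))

    def test_nonpositive_ids(self):
        with pytest.raises(ValidationError):
            RoiAtlas(region_ids=np.array([0, 1, 2]))

    def test_template_ids_must_exist(self):
        with pytest.raises(ValidationError, match="99"):
            RoiAtlas(region_ids=np.array([1, 2, 3]),
                     rsn_templates={"DMN": frozenset({99})})


class TestExtractSeries:
    def test_constant_image(self, image_atlas):
        shape = image_atlas.label_image.shape
        data = np.full(shape + (4,), 5.0)
        series = extract_series((data, 1.0), image_atlas)
        assert np.all(series.data == 5.0)
        assert series.data.shape == (4, image_atlas.n_regions)

    def test_two_voxel_region_mean(self, image_atlas):
        shape = image_atlas.label_image.shape
        data = np.zeros(shape + (2,))
        # region 1 occupies voxels (0,0,0) and (0,1,0)
        data[0, 0, 0, 0] = 1.0
        data[0, 1, 0, 0] = 3.0
        series = extract_series((data, 1.0), image_atlas)
        assert series.data[0, 0] == 2.0

    def test_one_voxel_regions_exact(self):
        ids = np.array([1, 2, 3])
        label = np.array([1, 2, 3]).reshape(3, 1, 1)
        atlas = RoiAtlas(region_ids=ids, label_image=label)
        data = np.arange(3 * 1 * 1 * 5, dtype=float).reshape(3, 1, 1, 5)
        series = extract_series((data, 1.0), atlas)
        for i in range(3):
            assert np.array_equal(series.data[:, i], data[i, 0, 0, :])

    def test_shape_mismatch(self, image_atlas):
        data = np.zeros((2, 2, 2, 3))
        with pytest.raises(ValidationError, match="grid"):
            extract_series((data, 1.0), image_atlas)

    def test_relabeling_permutes_columns(self, rng):
        ids = np.array([1, 2, 3, 4])
        label = np.array([1, 2, 3, 4]).reshape(4, 1, 1)
        data = rng.normal(size=(4, 1, 1, 6))
        atlas = RoiAtlas(region_ids=ids, label_image=label)
        base = extract_series((data, 1.0), atlas)
        # relabel regions 1<->4, 2<->3 and permute image accordingly
        perm = {1: 4, 2: 3, 3: 2, 4: 1}
        relabeled = np.vectorize(perm.get)(label)
        atlas2 = RoiAtlas(region_ids=ids, label_image=relabeled)
        permuted = extract_series((data, 1.0), atlas2)
        for old, new in perm.items():
            assert np.array_equal(permuted.data[:, new - 1],
                                  base.data[:, old - 1])


class TestPetRoiMeans:
    def test_constant_image(self, image_atlas):
        data = np.full(image_atlas.label_image.shape, 2.5)
        pet = pet_roi_means(data, image_atlas)
        assert np.all(pet.values == 2.5)

    def test_two_value_mean(self, image_atlas):
        data = np.zeros(image_atlas.label_image.shape)
        data[0, 0, 0] = 2.0
        data[0, 1, 0] = 4.0
        pet = pet_roi_means(data, image_atlas)
        assert pet.values[0] == 3.0

    def test_grid_mismatch(self, image_atlas):
        with pytest.raises(ValidationError, match="grid"):
            pet_roi_means(np.zeros((2, 2, 2)), image_atlas)


class TestConcatenateRuns:
    def _run(self, T=480, n=6, seed=0, tr=1.0, scale=1.0):
        r = np.random.default_rng(seed)
        return ParcellatedSeries(data=scale * r.normal(size=(T, n)), tr=tr)

    def test_time_dimension_sums(self):
        cat = concatenate_runs(self._run(), self._run(seed=1))
        assert cat.n_timepoints == 960
        assert cat.run_label == "concat"

    def test_standardize_zeroes_means(self):
        run = self._run(T=100)
        cat = concatenate_runs(run, run, standardize=True)
        assert np.allclose(cat.data.mean(axis=0), 0.0, atol=1e-12)

    def test_no_standardize_preserves_values(self):
        a, b = self._run(T=50), self._run(T=50, seed=1)
        cat = concatenate_runs(a, b, standardize=False)
        assert np.array_equal(cat.data, np.vstack([a.data, b.data]))

    def test_tr_mismatch(self):
        with pytest.raises(ValidationError, match="tr"):
            concatenate_runs(self._run(), self._run(tr=2.0))

    def test_region_mismatch(self):
        with pytest.raises(ValidationError, match="region"):
            concatenate_runs(self._run(n=6), self._run(n=7))


class TestTabularRoundTrips:
    def test_series_round_trip(self, image_atlas, tmp_path, rng):
        series = ParcellatedSeries(
            data=rng.normal(size=(20, image_atlas.n_regions)), tr=2.0)
        write_series(series, image_atlas, tmp_path / "s.tsv")
        back = read_series(tmp_path / "s.tsv", tr=2.0)
        assert np.allclose(back.data, series.data, atol=1e-9)

    def test_pet_round_trip(self, image_atlas, tmp_path, rng):
        pet = PetRoiMap(values=rng.normal(size=image_atlas.n_regions))
        write_pet_map(pet, image_atlas, tmp_path / "p.tsv")
        back = read_pet_map(tmp_path / "p.tsv", image_atlas)
        assert np.allclose(back.values, pet.values, atol=1e-9)

    def test_series_with_missing_values_rejected(self, tmp_path):
        (tmp_path / "bad.tsv").write_text("1\t2\n0.5\t\n0.1\t0.2\n")
        with pytest.raises(ValidationError, match="missing"):
            read_series(tmp_path / "bad.tsv", tr=1.0)
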