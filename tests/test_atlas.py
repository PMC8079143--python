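"""Atlas loading, hierarchy queries, and voxel-space spatial queries."""

import json

import numpy as np
import pytest
import tifffile

from brainscene.atlas import Atlas, load_atlas
from brainscene.errors import (
    AtlasLoadError,
    AtlasValidationError,
    EmptyRegionError,
    StructureLookupError,
)


class TestLoading:
    def test_mini_atlas_structure_count(self, atlas):
        assert len(atlas) == 5
        assert {n.acronym for n in atlas.nodes} == {"root", "CTX", "TH", "VISp", "MOs"}

    def test_missing_annotation_is_load_error(self, atlas_dir, tmp_path):
        broken = tmp_path / "broken"
        broken.mkdir()
        for f in ("structures.json", "metadata.json"):
            (broken / f).write_text((atlas_dir / f).read_text())
        with pytest.raises(AtlasLoadError, match="annotation.tiff"):
            load_atlas(broken)

    def test_parent_cycle_is_validation_error(self, atlas_dir, tmp_path):
        bundle = tmp_path / "cyclic"
        bundle.mkdir()
        records = json.loads((atlas_dir / "structures.json").read_text())
        records[1]["parent_id"] = records[2]["id"]  # CTX -> VISp -> CTX
        records[2]["parent_id"] = records[1]["id"]
        (bundle / "structures.json").write_text(json.dumps(records))
        (bundle / "metadata.json").write_text((atlas_dir / "metadata.json").read_text())
        (bundle / "annotation.tiff").write_bytes((atlas_dir / "annotation.tiff").read_bytes())
        with pytest.raises(AtlasValidationError, match="cycle"):
            load_atlas(bundle)

    def test_duplicate_acronym_rejected(self, atlas_dir, tmp_path):
        bundle = tmp_path / "dup"
        bundle.mkdir()
        records = json.loads((atlas_dir / "structures.json").read_text())
        records[3]["acronym"] = records[2]["acronym"]
        (bundle / "structures.json").write_text(json.dumps(records))
        (bundle / "metadata.json").write_text((atlas_dir / "metadata.json").read_text())
        (bundle / "annotation.tiff").write_bytes((atlas_dir / "annotation.tiff").read_bytes())
        with pytest.raises(AtlasValidationError, match="acronym"):
            load_atlas(bundle)

    def test_loading_twice_is_deterministic(self, atlas_dir):
        a1, a2 = load_atlas(atlas_dir), load_atlas(atlas_dir)
        assert a1.nodes == a2.nodes
        assert np.array_equal(a1.annotation.labels, a2.annotation.labels)


class TestHierarchy:
    def test_lookup_by_acronym_and_id(self, atlas):
        assert atlas.get_structure("root").parent_id is None
        node = atlas.get_structure("VISp")
        assert atlas.get_structure(node.id) is node

    def test_unknown_acronym_lists_suggestions(self, atlas):
        with pytest.raises(StructureLookupError, match="VIS"):
            atlas.get_structure("VISppp")

    def test_ancestor_chains(self, atlas):
        assert atlas.ancestors("root") == []
        assert [n.acronym for n in atlas.ancestors("VISp")] == ["CTX", "root"]
        assert [n.acronym for n in atlas.ancestors("TH")] == ["root"]

    def test_descendant_sets(self, atlas):
        assert atlas.descendants("VISp") == []
        assert {n.acronym for n in atlas.descendants("CTX")} == {"VISp", "MOs"}
        assert {n.acronym for n in atlas.descendants("root")} == {"CTX", "TH", "VISp", "MOs"}

    def test_ancestor_descendant_duality_exhaustive(self, atlas):
        """m is an ancestor of n exactly when n is a descendant of m."""
        for n in atlas.nodes:
            for m in atlas.nodes:
                up = any(a.id == m.id for a in atlas.ancestors(n.acronym))
                down = any(d.id == n.id for d in atlas.descendants(m.acronym))
                assert up == down


class TestSpatialQueries:
    def test_agrees_with_direct_voxel_indexing(self, atlas, rng):
        labels = atlas.annotation.labels
        res = atlas.annotation.resolution
        ext = atlas.annotation.extent_um
        pts = rng.uniform(-0.1 * ext, 1.1 * ext, (1000, 3))
        for p in pts:
            idx = np.floor(p / res).astype(int)
            off = (idx < 0).any() or (idx >= np.array(labels.shape)).any()
            expected = 0 if off else int(labels[tuple(idx)])
            node = atlas.structure_from_point(p)
            assert (0 if node is None else node.id) == expected

    def test_negative_coordinate_is_outside(self, atlas):
        assert atlas.structure_from_point([-1.0, 10.0, 10.0]) is None

    def test_voxel_center_maps_to_its_label(self, atlas):
        labels = atlas.annotation.labels
        res = atlas.annotation.resolution
        i, j, k = map(int, np.argwhere(labels == 4)[0])
        p = (np.array([i, j, k]) + 0.5) * res
        assert atlas.structure_from_point(p).acronym == "VISp"

    def test_boundary_point_floors_to_higher_voxel(self, atlas):
        """A point exactly on a voxel boundary belongs to the higher-index voxel."""
        labels = atlas.annotation.labels
        res = atlas.annotation.resolution
        vox = np.argwhere(labels == 4)
        # a VISp voxel whose lower AP neighbor has a different label
        for i, j, k in vox:
            if labels[i - 1, j, k] != 4:
                p = np.array([i, j + 0.5, k + 0.5]) * res  # exactly on the i boundary
                assert atlas.structure_from_point(p).id == 4
                return
        pytest.fail("no boundary voxel found")

    def test_point_in_region_respects_substructure_flag(self, atlas):
        labels = atlas.annotation.labels
        res = atlas.annotation.resolution
        p = (np.argwhere(labels == 4)[0] + 0.5) * res  # a VISp voxel center
        assert atlas.point_in_region(p, "CTX", include_substructures=True)
        assert not atlas.point_in_region(p, "CTX", include_substructures=False)
        assert atlas.point_in_region(p, "root", include_substructures=True)
        with pytest.raises(StructureLookupError):
            atlas.point_in_region(p, "NOPE", include_substructures=True)


class TestRegionMeshes:
    def test_annotation_derived_root_bbox_matches_voxel_extent(self, atlas):
        bare = Atlas(atlas.name, atlas.nodes, atlas.annotation, {})  # no mesh store
        mesh = bare.region_mesh("root")
        labels = atlas.annotation.labels
        res = atlas.annotation.resolution
        nz = np.argwhere(labels > 0)
        assert np.allclose(mesh.bounds[0], nz.min(axis=0) * res, atol=res.max())
        assert np.allclose(mesh.bounds[1], (nz.max(axis=0) + 1) * res, atol=res.max())

    def test_annotation_derived_root_volume_near_voxel_volume(self, atlas):
        bare = Atlas(atlas.name, atlas.nodes, atlas.annotation, {})
        mesh = bare.region_mesh("root")
        vox = (atlas.annotation.labels > 0).sum() * atlas.annotation.resolution.prod()
        assert abs(abs(mesh.volume) - vox) / vox < 0.15

    def test_parent_mesh_from_leaf_union(self, atlas):
        bare = Atlas(atlas.name, atlas.nodes, atlas.annotation, {})
        mesh = bare.region_mesh("CTX")
        assert len(mesh.faces) > 0
        vox = np.isin(atlas.annotation.labels, [4, 5]).sum() * atlas.annotation.resolution.prod()
        assert abs(abs(mesh.volume) - vox) / vox < 0.15

    def test_region_without_voxels_or_file_errors(self, atlas):
        from brainscene.atlas import AnnotationVolume, StructureNode

        nodes = list(atlas.nodes) + [
            StructureNode(99, "GHOST", "ghost region", atlas.root.id, (1, 2, 3))
        ]
        bare = Atlas(atlas.name, nodes, atlas.annotation, {})
        with pytest.raises(EmptyRegionError):
            bare.region_mesh("GHOST")

    def test_mesh_cache_returns_same_object(self, atlas):
        assert atlas.region_mesh("VISp") is atlas.region_mesh("VISp")
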