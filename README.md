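# hpvmleaf

Feature-preserving, multi-scale remeshing of broad (palmate-veined) plant
leaves for functional–structural plant modelling.

Canopy-scale light simulations need leaf meshes at controllable resolution,
but plain simplification of scanned leaf meshes destroys exactly the
features that drive the optics: the vein ridges, the margin outline, and the
blade's normals. `hpvmleaf` keeps those features explicit. A leaf is
represented by a **hierarchical parametric vein-and-margin (HPVM) skeleton**
— level-coded B-spline curves for the margin (split at sharp points),
wrinkle ridge crests, and primary/secondary/tertiary veins — plus a smooth
**auxiliary NURBS membrane** fitted through the skeleton. Remeshing at any
element size *l* then samples the skeleton and membrane and triangulates
with the constraints intact.

## The model and the pipeline

A B-spline basis function follows the Cox–de Boor recursion (with the
convention 0/0 = 0):

    N_{i,0}(u) = 1 if u_i <= u <= u_{i+1} else 0
    N_{i,k}(u) = (u - u_i)/(u_{i+k} - u_i) N_{i,k-1}(u)
               + (u_{i+k+1} - u)/(u_{i+k+1} - u_{i+1}) N_{i+1,k-1}(u)

and the rational tensor-product membrane is

    p(u,w) = Σ_i Σ_j N_{i,k}(u) N_{j,l}(w) W_ij P_ij / Σ_i Σ_j N_{i,k}(u) N_{j,l}(w) W_ij

with control net `P_ij`, weights `W_ij` (all 1 by default). Remeshing at
element size *l* proceeds in four steps:

1. **Curve sampling** — every skeleton curve is divided at equal arc length
   *l*; curves shorter than `alpha*l` are ignored (ignore factor `alpha`).
2. **Relaxation** — sampling points are fixed from low feature levels
   (margin) to high (tertiary veins). A test point closer than `beta1*l` to
   a fixed point is deleted; one between `beta1*l` and `beta2*l` is
   re-inserted on its own curve at arc distance `(beta1+beta2)/2*l`.
3. **Interior fill and calibration** — an advancing front marches inward
   from the margin in the surface's uv plane (candidate at height
   `sqrt(3)/2*l` on the perpendicular bisector of the active front; an
   existing node within radius `0.7*l` is reused). Interior points are
   lifted to 3D and snapped to the nearest scanned cloud point.
4. **Constrained Delaunay meshing** — points are triangulated in uv by the
   u-sorted single-vertex-strip divide-and-conquer algorithm (O(n log n));
   the discrete skeleton polylines are enforced as constrained edges, the
   mesh is restricted to the margin polygon, lifted to 3D and smoothed.

Quality is reported as in the field's standard remeshing tables: element
number, percentage of triangles whose minimum interior angle reaches 30°,
relative area error against a reference area, and the maximum distance from
the scanned cloud to the mesh.

Since no scanned leaves ship with the package, the `synthetic` module
generates palmate leaves with exact ground truth (lobed margin with sharp
points, a full vein hierarchy, wrinkles, grooves, blade fold, and a
scanner-like noisy cloud), which every stage is tested against.

## Worked example

```sh
hpvmleaf synth --out-dir leaf_out --seed 1          # synthetic leaf + cloud
hpvmleaf suite --sizes 5,10,20,40 --seed 1          # multi-scale series
```

or in Python:

```python
from hpvmleaf import LeafParams, generate_leaf, run_suite
from hpvmleaf.quality import QualityReport

leaf = generate_leaf(LeafParams(seed=1))
reports, results = run_suite(leaf, [5.0, 10.0, 20.0, 40.0], seed=1)
print(QualityReport.table(reports))
```

which prints (element sizes in mm):

```
 Size (mm)  Element number  Percentage of pass [%]  Area error [%]  Maximum distance error (mm)
         5            1432                   98.67            0.18                       0.8012
        10             358                   95.25            0.77                       0.9428
        20              98                   86.73            2.73                       1.5007
        40              26                   69.23           12.52                       6.2993
```

Reading the table: refining the element size from 40 mm to 5 mm raises the
element count from 26 to 1432 triangles while the approximation errors fall
— the mesh area converges to the true blade area (0.18 % error at 5 mm) and
no scanned point is farther than 0.80 mm from the mesh. At coarse sizes
quality is consciously sacrificed to keep the vein and margin features
(constrained edges force thin triangles), which is the intended trade-off
for multi-scale canopy models.

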