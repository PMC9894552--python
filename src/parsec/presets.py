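"""Reference parameter settings used by the calibration studies.

Magnitudes echo biobank-scale estimates for behavioral/anthropometric trait
pairs: direct-effect variances of 0.2-0.3, indirect (parental) variances an
order of magnitude smaller, modest positive direct-indirect covariances, and
a sibling shared-environment covariance around 0.15-0.2.  Both settings are
positive semi-definite with implied error variances well inside (0, 1).
"""

from .model import ParameterSet

__all__ = ["FULL_SETTING", "NULL_COV_DIR_SETTING"]

#: all 14 parameters nonzero; used for unbiasedness and SE-calibration studies
FULL_SETTING = ParameterSet(
    var_dir_1=0.30,
    var_dir_2=0.20,
    var_ind_1=0.05,
    var_ind_2=0.04,
    cov_dir=0.10,
    cov_ind=0.02,
    cov_dir_ind_11=0.03,
    cov_dir_ind_22=0.02,
    cov_dir1_ind2=0.015,
    cov_dir2_ind1=0.010,
    err_sib_cov_1=0.20,
    err_sib_cov_2=0.15,
    err_cross_same=0.10,
    err_cross_sib=0.08,
)

#: direct-effect covariance fixed at zero, everything else nonzero; used for
#: type-I-error calibration of the test on cov_dir
NULL_COV_DIR_SETTING = ParameterSet(
    var_dir_1=0.25,
    var_dir_2=0.25,
    var_ind_1=0.05,
    var_ind_2=0.05,
    cov_dir=0.0,
    cov_ind=0.02,
    cov_dir_ind_11=0.02,
    cov_dir_ind_22=0.02,
    cov_dir1_ind2=0.01,
    cov_dir2_ind1=0.01,
    err_sib_cov_1=0.15,
    err_sib_cov_2=0.15,
    err_cross_same=0.10,
    err_cross_sib=0.05,
)
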