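#!/usr/bin/env Rscript
# Export the Biobase sample ExpressionSet (26 samples x 500 features) as a
# CSV with samples as rows, for use with `dendrocut estimate`.
#
# Usage: Rscript scripts/export_expressionset.R out.csv
suppressMessages(library(Biobase))
args <- commandArgs(trailingOnly = TRUE)
if (length(args) != 1) stop("usage: export_expressionset.R out.csv")
data(sample.ExpressionSet)
dat <- t(exprs(sample.ExpressionSet))
write.csv(dat, args[1], quote = FALSE)
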