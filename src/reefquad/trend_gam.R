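# Beta-GAM engine for temporal cover trends (batch capable).
# Usage: Rscript trend_gam.R <in_csv> <out_json> <k> <n_curve> <penalized 0/1>
# Input columns: dataset, site, year, y [, reef_type]
# One model per dataset id:
#   y ~ reef_type + s(year, k) + s(year, by = ordered(reef_type), k) + s(site, bs = "re")
# with the reef-type terms dropped when a single reef type is present and
# the random effect dropped for a single site.  Family betar(logit), REML.
# penalized=0 fits the year smooths as fixed-df regression splines
# (fx=TRUE), giving Wald chi-square term tests with known df.

suppressPackageStartupMessages({
  library(mgcv)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
dat <- read.csv(args[1], stringsAsFactors = FALSE)
K <- as.integer(args[2 + 1])  # args: in, out, k, n_curve
out_path <- args[2]
n_curve <- as.integer(args[4])
penalized <- as.integer(args[5]) == 1L
fx <- if (penalized) "" else ", fx = TRUE"

fit_one <- function(di) {
  di$site <- factor(di$site)
  use_re <- nlevels(di$site) > 1
  use_reef <- "reef_type" %in% names(di) && length(unique(di$reef_type)) > 1
  kk <- min(K, length(unique(di$year)))
  terms <- c()
  if (use_reef) {
    levs <- sort(unique(di$reef_type))
    ref <- if ("patch" %in% levs) "patch" else levs[1]
    levs <- c(ref, setdiff(levs, ref))
    di$reef_type <- factor(di$reef_type, levels = levs)
    di$reef_o <- ordered(di$reef_type, levels = levs)
    terms <- c("reef_type", sprintf("s(year, k = %d%s)", kk, fx),
               sprintf("s(year, by = reef_o, k = %d%s)", kk, fx))
  } else {
    terms <- c(sprintf("s(year, k = %d%s)", kk, fx))
  }
  if (use_re) terms <- c(terms, 's(site, bs = "re")')
  form <- as.formula(paste("y ~", paste(terms, collapse = " + ")))
  g <- try(gam(form, data = di, family = betar(link = "logit"),
               method = "REML"), silent = TRUE)
  if (inherits(g, "try-error")) {
    return(list(converged = FALSE, error = as.character(g)))
  }
  s <- summary(g)
  pt <- s$p.table
  st <- s$s.table
  term_rows <- list()
  for (i in seq_len(nrow(pt))) {
    term_rows[[length(term_rows) + 1]] <- list(
      term = rownames(pt)[i], type = "parametric",
      statistic = unname(pt[i, "z value"]), p_value = unname(pt[i, "Pr(>|z|)"]))
  }
  if (!is.null(st) && nrow(st) > 0) {
    for (i in seq_len(nrow(st))) {
      term_rows[[length(term_rows) + 1]] <- list(
        term = rownames(st)[i], type = "smooth",
        statistic = unname(st[i, "Chi.sq"]), p_value = unname(st[i, "p-value"]))
    }
  }
  yrs <- seq(min(di$year), max(di$year), length.out = n_curve)
  if (use_reef) {
    nd <- expand.grid(year = yrs, reef_type = levels(di$reef_type))
    nd$reef_o <- ordered(nd$reef_type, levels = levels(di$reef_type))
  } else {
    nd <- data.frame(year = yrs)
    nd$reef_type <- NA
  }
  nd$site <- levels(di$site)[1]
  excl <- if (use_re) "s(site)" else NULL
  pr <- predict(g, newdata = nd, type = "link", se.fit = TRUE, exclude = excl)
  curves <- data.frame(
    year = nd$year, reef_type = as.character(nd$reef_type),
    mean = plogis(pr$fit),
    lo95 = plogis(pr$fit - 1.96 * pr$se.fit),
    hi95 = plogis(pr$fit + 1.96 * pr$se.fit))
  dr <- residuals(g, type = "deviance")
  list(
    converged = isTRUE(g$converged),
    terms = term_rows,
    deviance_explained = unname(s$dev.expl),
    n_obs = nrow(di),
    phi = unname(g$family$getTheta(TRUE)),
    curves = curves,
    diagnostics = list(
      deviance_residual_mean = mean(dr),
      deviance_residual_sd = sd(dr),
      deviance_residual_quantiles = unname(quantile(dr, c(0.025, 0.25, 0.5, 0.75, 0.975)))
    ),
    dropped_random_effect = !use_re
  )
}

res <- list()
for (ds in unique(dat$dataset)) {
  r <- fit_one(dat[dat$dataset == ds, , drop = FALSE])
  r$dataset <- ds
  res[[length(res) + 1]] <- r
}
write_json(res, out_path, auto_unbox = TRUE, digits = 10, na = "null",
           dataframe = "rows")
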